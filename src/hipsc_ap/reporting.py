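"""Result assembly: direction-of-effect verdicts and table/figure export.

The study's headline comparison is qualitative: for each intervention family
the sign of the change in rr and in repolarization duration relative to the
unperturbed model is compared against the experimentally observed direction
for the corresponding reference compound.  Experimental directions are
shipped as data (``data/expectations.json``), not hard-coded asserts —
disagreement between model and experiment is an expected, reportable
outcome, not an error.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FLAT_TOLERANCE",
    "DirectionVerdict",
    "load_expectations",
    "direction",
    "classify_directions",
    "export_results",
]

#: relative changes below this are classified "flat" (below protocol-level
#: numerical reproducibility noise)
FLAT_TOLERANCE = 0.005


@dataclasses.dataclass(frozen=True)
class DirectionVerdict:
    """Direction of effect of one intervention vs the experimental expectation."""

    model: str
    intervention: str
    family: str
    rr_direction: str           # up | down | flat
    apd90_direction: str
    expected_rr: str | None
    expected_repolarization: str | None
    matches_experiment: bool | None

    def row(self) -> dict:
        return dataclasses.asdict(self)


def load_expectations() -> dict[str, dict]:
    doc = json.loads(
        resources.files("hipsc_ap.data").joinpath("expectations.json").read_text()
    )
    return {k: v for k, v in doc.items() if isinstance(v, dict)}


def direction(value: float, baseline: float, tolerance: float = FLAT_TOLERANCE) -> str:
    if not (np.isfinite(value) and np.isfinite(baseline)) or baseline == 0:
        return "undefined"
    rel = (value - baseline) / abs(baseline)
    if abs(rel) < tolerance:
        return "flat"
    return "up" if rel > 0 else "down"


def _expectation_key(family: str, primary: float) -> str | None:
    if family == "gf_sweep":
        if primary < 1.0:
            return "if_inhibition"
        if primary > 1.0:
            return "if_augmentation"
        return None
    if family.startswith("diltiazem"):
        return "ical_block"
    if family.startswith("moxifloxacin"):
        return "ikr_block"
    return None


def classify_directions(
    table: pd.DataFrame,
    baseline: dict[str, tuple[float, float]],
    tolerance: float = FLAT_TOLERANCE,
) -> list[DirectionVerdict]:
    """Per-intervention up/down/flat verdicts against the expectations file.

    ``baseline`` maps model label to (rr_s, apd90_s) of the unperturbed run.
    Only rows with beating status are classified; verdict order follows the
    sorted table so it is invariant to the input row order.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    missing = [m for m in table["model"].unique() if m not in baseline]
    if missing:
        raise ValueError(f"missing baseline for model(s): {missing}")
    expectations = load_expectations()
    verdicts: list[DirectionVerdict] = []
    ordered = table.sort_values(["model", "family", "primary_fraction", "intervention"])
    for _, row in ordered.iterrows():
        if not str(row["status"]).startswith(("beating", "irregular")):
            continue
        rr0, apd0 = baseline[row["model"]]
        d_rr = direction(row["rr_s"], rr0, tolerance)
        d_apd = direction(row["apd90_s"], apd0, tolerance)
        key = _expectation_key(row["family"], row.get("primary_fraction", float("nan")))
        exp = expectations.get(key) if key else None
        if exp is None or "flat" in (d_rr, d_apd):
            match = None
        else:
            match = (d_rr == exp["rr"]) and (d_apd == exp["repolarization"])
        verdicts.append(DirectionVerdict(
            model=row["model"],
            intervention=row["intervention"],
            family=row["family"],
            rr_direction=d_rr,
            apd90_direction=d_apd,
            expected_rr=exp["rr"] if exp else None,
            expected_repolarization=exp["repolarization"] if exp else None,
            matches_experiment=match,
        ))
    return verdicts


def export_results(
    table: pd.DataFrame,
    verdicts: list[DirectionVerdict],
    reference=None,
    outdir: str | Path = "results",
    stem: str = "interventions",
) -> dict[str, Path]:
    """Write the result table (CSV), verdict summary (JSON) and one
    rr-vs-APD90 scatter per model variant (SVG, with surrogate bands)."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    paths: dict[str, Path] = {}

    ordered = table.sort_values(["model", "family", "primary_fraction", "intervention"])
    csv_path = outdir / f"{stem}.csv"
    ordered.to_csv(csv_path, index=False)
    paths["table"] = csv_path

    verdict_path = outdir / f"{stem}_verdicts.json"
    verdict_path.write_text(json.dumps([v.row() for v in verdicts], indent=1))
    paths["verdicts"] = verdict_path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = {"gf_sweep": "s", "diltiazem_I": "^", "moxifloxacin_II": "o",
               "moxifloxacin_III": "D"}
    for model in sorted(ordered["model"].unique()):
        sub = ordered[(ordered["model"] == model)
                      & ordered["status"].astype(str).str.startswith(("beating", "irregular"))]
        fig, ax = plt.subplots(figsize=(5, 4))
        if reference is not None:
            rr = np.linspace(*reference.rr_range_s, 100)
            mid = reference.curve(rr)
            ax.fill_between(rr, mid - reference.band_halfwidth_s,
                            mid + reference.band_halfwidth_s, alpha=0.25,
                            label=f"reference band ({reference.provenance})")
            ax.plot(rr, mid, lw=1)
        for fam, mk in markers.items():
            ff = sub[sub["family"] == fam]
            if len(ff):
                ax.scatter(ff["rr_s"], ff["apd90_s"], marker=mk, label=fam, s=30)
        ax.set_xlabel("rr (s)")
        ax.set_ylabel("APD90 (s)")
        ax.set_title(model)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig_path = outdir / f"{stem}_{model}.svg"
        fig.savefig(fig_path)
        plt.close(fig)
        paths[f"figure:{model}"] = fig_path
    return paths
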