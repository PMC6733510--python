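"""Hill-equation translation between compound concentration and channel block.

A compound is a set of (target conductance, IC50, Hill slope) inhibition
terms.  The fraction of conductance remaining at concentration C is

    s(C) = 1 / (1 + (C / IC50)^h)

so s(IC50) = 1/2 and s is strictly decreasing in C.  Scale factors are always
recomputed at full precision from IC50 and slope; rounded table values are
used only for validation.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources

from ._layout import SCALABLE
from .parameters import ModelParameters

__all__ = [
    "HillInhibition",
    "CompoundProfile",
    "hill_fraction",
    "concentration_for_fraction",
    "build_scaling",
    "build_scaling_at_concentration",
    "gf_sweep_factors",
    "apply_scaling",
    "load_compound_profiles",
]


@dataclasses.dataclass(frozen=True)
class HillInhibition:
    """One inhibition term: target conductance name, IC50 (µM), Hill slope."""

    target: str
    ic50_uM: float
    hill_slope: float

    def __post_init__(self) -> None:
        if self.ic50_uM <= 0:
            raise ValueError("IC50 must be > 0")
        if self.hill_slope <= 0:
            raise ValueError("Hill slope must be > 0")


@dataclasses.dataclass(frozen=True)
class CompoundProfile:
    """Named primary inhibition plus off-target inhibitions of one compound."""

    compound: str
    primary: HillInhibition
    off_targets: tuple[HillInhibition, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        targets = [self.primary.target] + [o.target for o in self.off_targets]
        if len(set(targets)) != len(targets):
            raise ValueError(f"duplicate targets in profile: {targets}")
        unknown = [t for t in targets if t not in SCALABLE]
        if unknown:
            raise ValueError(
                f"unknown conductance target(s) {unknown}; valid: {list(SCALABLE)}"
            )

    @property
    def all_terms(self) -> tuple[HillInhibition, ...]:
        return (self.primary, *self.off_targets)


def hill_fraction(concentration_uM: float, inhibition: HillInhibition) -> float:
    """Fraction of conductance remaining at a concentration (1 at C = 0)."""
    if concentration_uM < 0:
        raise ValueError("concentration must be >= 0")
    if concentration_uM == 0:
        return 1.0
    return 1.0 / (1.0 + (concentration_uM / inhibition.ic50_uM) ** inhibition.hill_slope)


def concentration_for_fraction(fraction: float, inhibition: HillInhibition) -> float:
    """Concentration (µM) at which ``hill_fraction`` equals ``fraction``.

    Exact inverse of the Hill equation; only defined on (0, 1).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    return inhibition.ic50_uM * (1.0 / fraction - 1.0) ** (1.0 / inhibition.hill_slope)


def build_scaling(
    profile: CompoundProfile, primary_fraction: float
) -> tuple[dict[str, float], float]:
    """Scale factors for all targets at the primary target's set point.

    The concentration implied by the primary fraction is obtained from the
    inverse Hill equation, then every off-target fraction is evaluated at
    that concentration.  Returns ``(scaling, concentration_uM)`` with all
    entries at full precision.
    """
    conc = concentration_for_fraction(primary_fraction, profile.primary)
    scaling = {profile.primary.target: primary_fraction}
    for term in profile.off_targets:
        scaling[term.target] = hill_fraction(conc, term)
    return scaling, conc


def build_scaling_at_concentration(
    profile: CompoundProfile, concentration_uM: float
) -> dict[str, float]:
    """Scale factors for all targets (primary included) at a concentration."""
    return {term.target: hill_fraction(concentration_uM, term)
            for term in profile.all_terms}


def gf_sweep_factors() -> list[float]:
    """The funny-current conductance sweep: 0–400% of the published g_f."""
    return [0.0, 0.5, 0.9, 0.99, 1.01, 1.1, 1.5, 2.0, 3.0, 4.0]


def apply_scaling(params: ModelParameters, scaling: dict[str, float]) -> ModelParameters:
    """Multiply named maximal conductances by their factors; all else unchanged."""
    unknown = [k for k in scaling if k not in SCALABLE]
    if unknown:
        raise KeyError(
            f"unknown scaling target(s) {unknown}; valid names: {list(SCALABLE)}"
        )
    for k, v in scaling.items():
        if v < 0:
            raise ValueError(f"scale factor for {k} must be >= 0, got {v}")
    return params.replace(**{k: params.values[k] * v for k, v in scaling.items()})


def load_compound_profiles() -> dict[str, CompoundProfile | dict]:
    """The shipped compound profiles (three Hill profiles plus the two
    compounds modelled as pure g_f scaling)."""
    raw = json.loads(
        resources.files("hipsc_ap.data").joinpath("compounds.json").read_text()
    )
    out: dict[str, CompoundProfile | dict] = {}
    for key, doc in raw.items():
        if doc.get("gf_scaling_only"):
            out[key] = doc
            continue
        profile = CompoundProfile(
            compound=doc["compound"],
            primary=HillInhibition(
                doc["primary"]["target"],
                doc["primary"]["ic50_uM"],
                doc["primary"]["hill_slope"],
            ),
            off_targets=tuple(
                HillInhibition(o["target"], o["ic50_uM"], o["hill_slope"])
                for o in doc.get("off_targets", ())
            ),
            provenance=doc.get("provenance", ""),
        )
        out[key] = profile
    return out


def profile_grid(key: str) -> tuple[CompoundProfile, list[tuple[str, float]]]:
    """A profile plus its study grid as (mode, value) pairs.

    ``mode`` is "fraction" for profiles driven by primary-target set points
    and "concentration" for the alternative Moxifloxacin profile, whose grid
    is the concentration series implied by the first profile.
    """
    raw = json.loads(
        resources.files("hipsc_ap.data").joinpath("compounds.json").read_text()
    )[key]
    profile = load_compound_profiles()[key]
    if not isinstance(profile, CompoundProfile):
        raise ValueError(f"profile {key!r} has no Hill terms")
    if "primary_fraction_grid" in raw:
        grid = [("fraction", float(v)) for v in raw["primary_fraction_grid"]]
    else:
        grid = [("concentration", float(v)) for v in raw["concentration_grid_uM"]]
    return profile, grid
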