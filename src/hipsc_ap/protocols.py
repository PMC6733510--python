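"""Simulation protocols: limit-cycle perturbation, acute perturbation at the
diastolic minimum, and the sweep drivers producing rr-vs-APD90 tables.

The reference protocol runs the unperturbed model to its limit cycle
(5000 s), applies a conductance scaling, runs a further 5000 s and analyzes
the last 1000 s; rr and APD90 sequences are averaged over the window.  A
documented scaled-down configuration (800 s + 800 s, 400 s window) is
provided for routine use and carries an explicit ``scaled_down`` flag in all
outputs.

The acute protocol instead places the scaling exactly at the diastolic
minimum between two action potentials and reports the APD90 of the first
post-perturbation beat and the rr between the first and second
post-perturbation peaks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np

from . import biomarkers as bm
from .model import advance, integrate
from .parameters import ModelParameters
from .pharmacology import (
    apply_scaling,
    build_scaling,
    build_scaling_at_concentration,
    gf_sweep_factors,
    profile_grid,
)

__all__ = [
    "ProtocolConfig",
    "FULL_PROTOCOL",
    "SCALED_DOWN_PROTOCOL",
    "LimitCycleResult",
    "InterventionResult",
    "run_limit_cycle",
    "run_perturbed",
    "run_acute",
    "standard_interventions",
    "run_intervention_set",
]

#: no detected peak within this many simulated seconds => quiescent
QUIESCENCE_WINDOW = 30.0
#: limit-cycle quality: rr coefficient of variation below this over the window
LIMIT_CYCLE_CV = 0.01


@dataclasses.dataclass(frozen=True)
class ProtocolConfig:
    """Durations (s), output grid and solver tolerances of one protocol run."""

    pre_duration: float = 5000.0
    post_duration: float = 5000.0
    analysis_window: float = 1000.0
    output_step: float = 5e-4
    rtol: float = 1e-7
    atol: float = 1e-9
    acute_horizon: float = 30.0
    scaled_down: bool = False

    def __post_init__(self) -> None:
        if self.post_duration <= 0 or self.analysis_window <= 0:
            raise ValueError("durations must be > 0")
        if self.pre_duration < 0:
            raise ValueError("pre-perturbation duration must be >= 0")
        if self.analysis_window > self.post_duration:
            raise ValueError("analysis window must not exceed the post-run")
        if self.pre_duration and self.analysis_window > self.pre_duration:
            raise ValueError("analysis window must not exceed the pre-run")


FULL_PROTOCOL = ProtocolConfig()
SCALED_DOWN_PROTOCOL = ProtocolConfig(pre_duration=800.0, post_duration=800.0,
                                      analysis_window=400.0, scaled_down=True)


@dataclasses.dataclass
class LimitCycleResult:
    """Outcome of the unperturbed pre-run."""

    state: np.ndarray                 # state at the end of the pre-run
    series: bm.BiomarkerSeries | None
    trace: object                     # SimulationResult of the analysis window
    status: str                       # beating | quiescent | irregular
    rr_cv: float
    converged: bool                   # rr CV below the limit-cycle criterion
    scaled_down: bool = False


@dataclasses.dataclass
class InterventionResult:
    """One row of the rr-vs-APD90 result tables."""

    label: str
    scaling: dict[str, float]
    concentration_uM: float
    mean_rr: float
    mean_apd90: float
    sd_rr: float
    n_beats: int
    status: str                       # beating | quiescent | irregular | failed
    series: bm.BiomarkerSeries | None = None
    scaled_down: bool = False
    mode: str = "limit_cycle"         # or "acute"

    def row(self) -> dict:
        return {
            "intervention": self.label,
            "scaling": json.dumps(self.scaling, sort_keys=True),
            "concentration_uM": self.concentration_uM,
            "rr_s": self.mean_rr,
            "apd90_s": self.mean_apd90,
            "sd_rr_s": self.sd_rr,
            "n_beats": self.n_beats,
            "status": self.status,
            "mode": self.mode,
            "scaled_down": self.scaled_down,
        }


def _status(series: bm.BiomarkerSeries | None, trace) -> str:
    if series is None or series.n_peaks == 0:
        return "quiescent"
    last_peak = series.beats.peak_times[-1] if series.beats is not None else -np.inf
    if trace is not None and trace.t[-1] - last_peak > QUIESCENCE_WINDOW:
        return "quiescent"
    if series.n_peaks < 2:
        return "quiescent"
    if "irregular" in series.flags:
        return "irregular"
    return "beating"


def run_limit_cycle(
    params: ModelParameters,
    initial: np.ndarray,
    config: ProtocolConfig = FULL_PROTOCOL,
) -> LimitCycleResult:
    """Unperturbed run to the limit cycle; biomarkers over the final window.

    With ``pre_duration == 0`` the initial state is returned unchanged
    (degenerate but well-defined: no pre-run was requested).
    """
    if config.pre_duration == 0:
        return LimitCycleResult(state=np.asarray(initial, float).copy(), series=None,
                                trace=None, status="not_run", rr_cv=float("nan"),
                                converged=False, scaled_down=config.scaled_down)
    settle = config.pre_duration - config.analysis_window
    state = np.asarray(initial, float)
    if settle > 0:
        state, _ = advance(state, params, settle, rtol=config.rtol, atol=config.atol)
    trace = integrate(state, params, config.analysis_window, config.output_step,
                      rtol=config.rtol, atol=config.atol,
                      annotation="limit_cycle_window")
    series = bm.extract(trace.t, trace.Vm, trace.dVmdt)
    status = _status(series, trace)
    cv = series.rr_cv if series.rr.size else float("nan")
    return LimitCycleResult(
        state=trace.final_state,
        series=series if status != "quiescent" else series,
        trace=trace,
        status=status,
        rr_cv=cv,
        converged=bool(np.isfinite(cv) and cv < LIMIT_CYCLE_CV),
        scaled_down=config.scaled_down,
    )


def run_perturbed(
    limit_state: np.ndarray,
    params: ModelParameters,
    scaling: dict[str, float],
    config: ProtocolConfig = FULL_PROTOCOL,
    label: str = "",
    concentration_uM: float = float("nan"),
) -> InterventionResult:
    """Apply a conductance scaling at t=0 and analyze the final window."""
    scaled = apply_scaling(params, scaling)
    state = np.asarray(limit_state, float)
    settle = config.post_duration - config.analysis_window
    try:
        if settle > 0:
            state, _ = advance(state, scaled, settle, rtol=config.rtol, atol=config.atol)
        trace = integrate(state, scaled, config.analysis_window, config.output_step,
                          rtol=config.rtol, atol=config.atol, annotation=label)
    except Exception as exc:  # integration failure -> partial result
        return InterventionResult(label=label, scaling=dict(scaling),
                                  concentration_uM=concentration_uM,
                                  mean_rr=float("nan"), mean_apd90=float("nan"),
                                  sd_rr=float("nan"), n_beats=0,
                                  status=f"failed: {exc}",
                                  scaled_down=config.scaled_down)
    series = bm.extract(trace.t, trace.Vm, trace.dVmdt)
    status = _status(series, trace)
    beating = status in ("beating", "irregular")
    return InterventionResult(
        label=label,
        scaling=dict(scaling),
        concentration_uM=concentration_uM,
        mean_rr=series.mean_rr if beating else float("nan"),
        mean_apd90=series.mean_apd90 if beating else float("nan"),
        sd_rr=series.sd_rr if beating else float("nan"),
        n_beats=int(series.rr.size),
        status=status if trace.ok else "failed: truncated",
        series=series,
        scaled_down=config.scaled_down,
    )


def locate_diastolic_minimum(trace) -> float:
    """Time of the diastolic minimum between the first two detected peaks.

    Grid minimum refined by a local parabolic (3-point quadratic) fit.
    """
    series = bm.extract(trace.t, trace.Vm, trace.dVmdt)
    if series.n_peaks < 2:
        raise ValueError("need at least two peaks to locate a diastolic minimum")
    from scipy.signal import find_peaks

    idx, _ = find_peaks(trace.Vm, prominence=bm.PROMINENCE)
    i0, i1 = int(idx[0]), int(idx[1])
    k = i0 + int(np.argmin(trace.Vm[i0:i1 + 1]))
    if k <= i0 or k >= i1:
        return float(trace.t[k])
    t3 = trace.t[k - 1:k + 2]
    v3 = trace.Vm[k - 1:k + 2]
    denom = (v3[0] - 2 * v3[1] + v3[2])
    if denom <= 0:
        return float(t3[1])
    shift = 0.5 * (v3[0] - v3[2]) / denom
    return float(t3[1] + shift * (t3[1] - t3[0]))


def run_acute(
    limit_state: np.ndarray,
    params: ModelParameters,
    scaling: dict[str, float],
    config: ProtocolConfig = FULL_PROTOCOL,
    label: str = "",
    concentration_uM: float = float("nan"),
) -> InterventionResult:
    """Acute protocol: scaling applied exactly at the diastolic minimum.

    Reports the rr between the first and second post-perturbation peaks and
    the APD90 of the first post-perturbation action potential.
    """
    state = np.asarray(limit_state, float)
    # search run: find the first two beats and the minimum between them
    search = integrate(state, params, config.acute_horizon, config.output_step,
                       rtol=config.rtol, atol=config.atol, annotation="acute_search")
    try:
        t_min = locate_diastolic_minimum(search)
    except ValueError:
        return InterventionResult(label=label, scaling=dict(scaling),
                                  concentration_uM=concentration_uM,
                                  mean_rr=float("nan"), mean_apd90=float("nan"),
                                  sd_rr=float("nan"), n_beats=0,
                                  status="quiescent", scaled_down=config.scaled_down,
                                  mode="acute")
    # advance the unperturbed model exactly to the minimum, then perturb
    at_min, _ = advance(state, params, t_min, rtol=config.rtol, atol=config.atol)
    scaled = apply_scaling(params, scaling)
    post = integrate(at_min, scaled, config.acute_horizon, config.output_step,
                     rtol=config.rtol, atol=config.atol, t0=t_min,
                     annotation=f"acute:{label}")
    # prepend the pre-perturbation beat so the first post-AP has a preceding
    # peak and diastolic minimum for its APD90 reference
    keep = search.t <= t_min
    t = np.concatenate([search.t[keep], post.t])
    vm = np.concatenate([search.Vm[keep], post.Vm])
    dvdt = np.concatenate([search.dVmdt[keep], post.dVmdt])
    series = bm.extract(t, vm, dvdt)
    # beats strictly after the perturbation
    if series.beats is None:
        post_mask = np.empty(0, bool)
    else:
        post_mask = series.beats.peak_times > t_min
    n_post = int(post_mask.sum()) if series.beats is not None else 0
    if n_post < 2:
        return InterventionResult(label=label, scaling=dict(scaling),
                                  concentration_uM=concentration_uM,
                                  mean_rr=float("nan"), mean_apd90=float("nan"),
                                  sd_rr=float("nan"), n_beats=n_post,
                                  status="quiescent", scaled_down=config.scaled_down,
                                  mode="acute")
    post_times = series.beats.peak_times[post_mask]
    post_apd = series.beats.apd90[post_mask]
    acute_rr = float(post_times[1] - post_times[0])
    acute_apd90 = float(post_apd[0])
    return InterventionResult(
        label=label,
        scaling=dict(scaling),
        concentration_uM=concentration_uM,
        mean_rr=acute_rr,
        mean_apd90=acute_apd90,
        sd_rr=0.0,
        n_beats=2,
        status="beating",
        series=series,
        scaled_down=config.scaled_down,
        mode="acute",
    )


# ---------------------------------------------------------------------------
# Sweep drivers
# ---------------------------------------------------------------------------

def standard_interventions() -> list[dict]:
    """The full study set: g_f sweep plus the three compound grids (22 rows)."""
    items: list[dict] = []
    for f in gf_sweep_factors():
        items.append({"label": f"gf_x{f:g}", "scaling": {"gf": f},
                      "concentration_uM": float("nan"), "family": "gf_sweep",
                      "primary": f})
    for key in ("diltiazem_I", "moxifloxacin_II", "moxifloxacin_III"):
        profile, grid = profile_grid(key)
        for mode, value in grid:
            if mode == "fraction":
                scaling, conc = build_scaling(profile, value)
            else:
                scaling = build_scaling_at_concentration(profile, value)
                conc = value
            items.append({
                "label": f"{key}_{mode[0]}{value:g}",
                "scaling": scaling,
                "concentration_uM": conc,
                "family": key,
                "primary": scaling[profile.primary.target],
            })
    return items


def _cache_key(params: ModelParameters, scaling: dict, config: ProtocolConfig,
               mode: str) -> str:
    payload = {
        "params": params.pack().tobytes().hex(),
        "scaling": sorted(scaling.items()),
        "config": dataclasses.asdict(config),
        "mode": mode,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_intervention_set(
    variants: dict[str, tuple[ModelParameters, np.ndarray]],
    interventions: list[dict] | None = None,
    config: ProtocolConfig = FULL_PROTOCOL,
    mode: str = "limit_cycle",
    cache: dict | None = None,
):
    """One InterventionResult row per (model variant, intervention).

    ``variants`` maps a variant label to ``(params, initial_state)``.  Rows
    are produced in deterministic order; per-run results are memoized in
    ``cache`` keyed by a content hash of params + scaling + config, so a
    partially completed sweep can be resumed.  Individual failures are
    recorded in their row and do not abort the set.
    """
    import pandas as pd

    if interventions is None:
        interventions = standard_interventions()
    if cache is None:
        cache = {}
    runner = run_acute if mode == "acute" else run_perturbed
    rows = []
    results: list[tuple[str, InterventionResult]] = []
    for model_label in sorted(variants):
        params, y0 = variants[model_label]
        lc_key = _cache_key(params, {}, config, "limit_cycle_state")
        if lc_key not in cache:
            cache[lc_key] = run_limit_cycle(params, y0, config)
        lc = cache[lc_key]
        for item in interventions:
            key = _cache_key(params, item["scaling"], config, mode)
            if key not in cache:
                cache[key] = runner(lc.state, params, item["scaling"], config,
                                    label=item["label"],
                                    concentration_uM=item["concentration_uM"])
            res = cache[key]
            results.append((model_label, res))
            row = {"model": model_label, "family": item.get("family", ""),
                   "primary_fraction": item.get("primary", float("nan"))}
            row.update(res.row())
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, results
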