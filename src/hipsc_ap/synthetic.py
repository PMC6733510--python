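"""Ground-truth generators: parametric AP trains and surrogate reference curves.

The AP-train generator produces voltage traces with exactly known period,
upstroke time, amplitude and APD90, so the biomarker pipeline can be tested
independently of the ODE models.  Two waveform families are provided:

* ``triangular`` — piecewise linear; every marker has a closed form and the
  biomarker pipeline's linear interpolation is exact on it.
* ``smooth`` — product-of-logistics beats with a continuous derivative, so
  the maximum-upstroke-velocity instant is well defined; ground truth is
  computed from the analytic waveform by high-precision root finding,
  independent of any sampled trace.

The surrogate reference curves stand in for experimental repolarization-vs-rr
polynomial fits whose coefficients are not printed anywhere available; they
are labelled as synthetic in the shipped fixture and are used only for band
plots and inside/outside classification.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "ApTrainSpec",
    "ApTrain",
    "generate_ap_train",
    "ExperimentalReference",
    "surrogate_reference",
]


@dataclasses.dataclass(frozen=True)
class ApTrainSpec:
    """Parameters of a synthetic action-potential train (SI units)."""

    period: float = 1.0
    apd90: float = 0.3
    peak_voltage: float = 0.03
    diastolic_voltage: float = -0.075
    upstroke_duration: float = 0.002
    family: str = "smooth"
    noise_sd: float = 0.0
    duration: float = 10.0
    seed: int = 0
    output_step: float = 1e-3

    def __post_init__(self) -> None:
        if not self.apd90 < self.period:
            raise ValueError("apd90 must be smaller than the period")
        if not self.upstroke_duration < self.apd90:
            raise ValueError("upstroke duration must be smaller than apd90")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.peak_voltage <= self.diastolic_voltage:
            raise ValueError("peak voltage must exceed diastolic voltage")
        if self.family not in ("triangular", "smooth"):
            raise ValueError("family must be 'triangular' or 'smooth'")
        if self.apd90 / 0.9 > 0.95 * self.period:
            raise ValueError("apd90 too close to the period: no diastole left")


@dataclasses.dataclass
class ApTrain:
    """Generated trace plus its ground-truth markers."""

    t: np.ndarray
    Vm: np.ndarray
    dVmdt: np.ndarray
    true_peak_times: np.ndarray
    true_upstroke_times: np.ndarray
    true_apd90: float
    spec: ApTrainSpec


def _triangular(spec: ApTrainSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    amp = spec.peak_voltage - spec.diastolic_voltage
    u = spec.upstroke_duration
    fall = (spec.apd90 - u) / 0.9
    first = 0.3 * spec.period
    n_beats = int((spec.duration - first - u - fall) // spec.period) + 1
    starts = first + spec.period * np.arange(n_beats)

    vm = np.full_like(t, spec.diastolic_voltage)
    dv = np.zeros_like(t)
    for s in starts:
        rise = (t >= s) & (t < s + u)
        vm[rise] = spec.diastolic_voltage + amp * (t[rise] - s) / u
        dv[rise] = amp / u
        dec = (t >= s + u) & (t < s + u + fall)
        vm[dec] = spec.peak_voltage - amp * (t[dec] - s - u) / fall
        dv[dec] = -amp / fall
    return vm, dv, starts + u, starts, spec.apd90


def _smooth_beat(tau: np.ndarray, t_r: float, t_f: float, w_up: float,
                 w_rep: float) -> np.ndarray:
    return 1.0 / ((1.0 + np.exp(-(tau - t_r) / w_up))
                  * (1.0 + np.exp((tau - t_f) / w_rep)))


def _smooth(spec: ApTrainSpec, t: np.ndarray):
    amp = spec.peak_voltage - spec.diastolic_voltage
    w_up = spec.upstroke_duration / 2.0
    w_rep = max(0.012, 0.04 * spec.apd90)
    t_r = 0.0  # beat-local rise midpoint

    def shape(x):
        return _smooth_beat(np.asarray(x, float), t_r, t_f, w_up, w_rep)

    def dshape(x):
        e1 = np.exp(-(x - t_r) / w_up)
        e2 = np.exp((x - t_f) / w_rep)
        s = 1.0 / ((1.0 + e1) * (1.0 + e2))
        return s * (e1 / (w_up * (1.0 + e1)) - e2 / (w_rep * (1.0 + e2)))

    def beat_apd90(tf_val):
        nonlocal t_f
        t_f = tf_val
        t_peak = minimize_scalar(lambda x: -shape(x), bounds=(t_r, t_f + 10 * w_rep),
                                 method="bounded",
                                 options={"xatol": 1e-12}).x
        t_up = minimize_scalar(lambda x: -dshape(x),
                               bounds=(t_r - 10 * w_up, t_peak),
                               method="bounded", options={"xatol": 1e-12}).x
        v_peak = shape(t_peak)
        level = v_peak - 0.9 * v_peak  # diastolic baseline is 0 in beat units
        t_cross = brentq(lambda x: shape(x) - level, t_peak, t_f + 30 * w_rep,
                         xtol=1e-12)
        return float(t_cross - t_up), float(t_up), float(t_peak)

    t_f = spec.apd90  # initial guess; calibrated so true APD90 == spec.apd90
    lo, hi = spec.upstroke_duration, spec.period
    tf_cal = brentq(lambda v: beat_apd90(v)[0] - spec.apd90, lo, hi, xtol=1e-10)
    true_apd90, t_up_loc, t_peak_loc = beat_apd90(tf_cal)

    first = 0.3 * spec.period
    n_beats = int((spec.duration - first - tf_cal - 10 * w_rep) // spec.period) + 1
    starts = first + spec.period * np.arange(n_beats)
    vm = np.full_like(t, spec.diastolic_voltage)
    dv = np.zeros_like(t)
    for s in starts:
        local = t - s
        mask = (local > -20 * w_up) & (local < tf_cal + 40 * w_rep)
        vm[mask] += amp * shape(local[mask])
        dv[mask] += amp * dshape(local[mask])
    return vm, dv, starts + t_peak_loc, starts + t_up_loc, true_apd90


def generate_ap_train(spec: ApTrainSpec) -> ApTrain:
    """Generate a spontaneous AP train with known markers.

    The returned derivative trace is the analytic (noise-free) derivative of
    the waveform, mirroring how the ODE pipeline evaluates dVm/dt from the
    right-hand side rather than from sampled differences.  Reproducible for
    a fixed seed.
    """
    n = int(round(spec.duration / spec.output_step))
    t = np.arange(n + 1) * spec.output_step
    if spec.family == "triangular":
        vm, dv, peaks, ups, apd = _triangular(spec, t)
    else:
        vm, dv, peaks, ups, apd = _smooth(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vm = vm + rng.normal(0.0, spec.noise_sd, size=vm.shape)
    return ApTrain(t=t, Vm=vm, dVmdt=dv, true_peak_times=peaks,
                   true_upstroke_times=ups, true_apd90=apd, spec=spec)


# ---------------------------------------------------------------------------
# Surrogate experimental reference curves
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ExperimentalReference:
    """Second-order polynomial repolarization-vs-rr curve with a prediction band.

    ``provenance`` is always "surrogate" for the shipped fixtures: the
    experimental fit coefficients are not publicly printed.
    """

    coefficients: tuple[float, float, float]   # c0 + c1*rr + c2*rr^2
    band_halfwidth_s: float
    rr_range_s: tuple[float, float]
    provenance: str = "surrogate"

    def __post_init__(self) -> None:
        if self.band_halfwidth_s <= 0:
            raise ValueError("band half-width must be > 0")

    def curve(self, rr: np.ndarray) -> np.ndarray:
        rr = np.asarray(rr, dtype=float)
        c0, c1, c2 = self.coefficients
        return c0 + c1 * rr + c2 * rr * rr

    def classify(self, rr: float, repolarization: float) -> str:
        """"inside" when the point lies within the prediction band over the
        curve's dynamic range, else "outside"."""
        lo, hi = self.rr_range_s
        if not lo <= rr <= hi:
            return "outside"
        mid = float(self.curve(rr))
        return "inside" if abs(repolarization - mid) <= self.band_halfwidth_s \
            else "outside"


def surrogate_reference(name: str = "rate_modulation") -> ExperimentalReference:
    """Load a shipped surrogate reference curve (synthetic fixture)."""
    doc = json.loads(
        resources.files("hipsc_ap.data").joinpath("surrogate_reference.json").read_text()
    )
    try:
        cfg = doc["curves"][name]
    except KeyError:
        raise ValueError(
            f"unknown reference curve {name!r}; available: {sorted(doc['curves'])}"
        ) from None
    return ExperimentalReference(
        coefficients=tuple(cfg["coefficients"]),
        band_halfwidth_s=cfg["band_halfwidth_s"],
        rr_range_s=tuple(cfg["rr_range_s"]),
        provenance=doc["provenance"],
    )
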