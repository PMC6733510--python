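"""Per-beat biomarkers of a voltage trace: peaks, rr intervals, APD90.

Definitions
-----------
* Beats are local maxima of Vm with at least 20 mV prominence (separates
  action potentials from diastolic-depolarization wiggle); boundary samples
  are never peaks.
* rr is the difference between successive peak times.
* APD90 of a beat runs from the moment of maximum upstroke velocity to the
  first downward crossing of the 90 %-repolarization level after the peak,
  where the level is per-beat: Vpeak - 0.9 * (Vpeak - Vdia), with Vdia the
  diastolic minimum between the previous and the current peak.  The crossing
  is located by linear interpolation between samples, so it is exact on
  piecewise-linear input.
* The first beat of a window carries no APD90 (it has no preceding
  diastolic minimum) and the rr/APD90 sequences are averaged over all
  complete beats to suppress numerical round-off.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PROMINENCE",
    "BeatMarkers",
    "BiomarkerSeries",
    "detect_peaks",
    "rr_intervals",
    "apd90",
    "extract",
]

#: minimum peak prominence, V
PROMINENCE = 0.020

#: rr standard deviation above this fraction of the mean flags an irregular rhythm
IRREGULAR_CV = 0.05


@dataclasses.dataclass
class BeatMarkers:
    """Markers of the complete beats of one trace (arrays share length)."""

    peak_times: np.ndarray     # s
    peak_voltages: np.ndarray  # V
    upstroke_times: np.ndarray  # s, at max dV/dt
    amplitudes: np.ndarray     # V, peak minus preceding diastolic minimum
    apd90: np.ndarray          # s; NaN where repolarization is incomplete


@dataclasses.dataclass
class BiomarkerSeries:
    """rr/APD90 series with means and quality flags for one analysis window."""

    rr: np.ndarray
    apd90: np.ndarray
    beats: BeatMarkers | None
    n_peaks: int
    flags: tuple[str, ...] = ()

    @property
    def mean_rr(self) -> float:
        return float(np.mean(self.rr)) if self.rr.size else float("nan")

    @property
    def mean_apd90(self) -> float:
        ok = self.apd90[np.isfinite(self.apd90)]
        return float(np.mean(ok)) if ok.size else float("nan")

    @property
    def sd_rr(self) -> float:
        return float(np.std(self.rr)) if self.rr.size else float("nan")

    @property
    def rr_cv(self) -> float:
        return self.sd_rr / self.mean_rr if self.rr.size else float("nan")

    def to_frame(self):
        import pandas as pd

        if self.beats is None:
            return pd.DataFrame()
        b = self.beats
        return pd.DataFrame({
            "beat": np.arange(len(b.peak_times)),
            "t_peak_s": b.peak_times,
            "t_upstroke_s": b.upstroke_times,
            "amplitude_V": b.amplitudes,
            "apd90_s": b.apd90,
        })


def detect_peaks(t: np.ndarray, vm: np.ndarray,
                 prominence: float = PROMINENCE) -> tuple[np.ndarray, np.ndarray]:
    """Times and voltages of local maxima exceeding the prominence threshold."""
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if t.size < 3:
        return np.empty(0), np.empty(0)
    idx, _ = find_peaks(vm, prominence=prominence)
    return t[idx], vm[idx]


def rr_intervals(peak_times: np.ndarray) -> np.ndarray:
    """Successive differences of peak times; empty when fewer than 2 peaks."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        return np.empty(0)
    return np.diff(peak_times)


def _interp_crossing(t0, v0, t1, v1, level):
    # downward crossing of `level` on the segment (t0,v0)-(t1,v1)
    return t0 + (v0 - level) / (v0 - v1) * (t1 - t0)


def apd90(t: np.ndarray, vm: np.ndarray, dvdt: np.ndarray,
          i_prev_peak: int, i_peak: int, i_next_peak: int | None) -> tuple[float, float, float]:
    """APD90 of the beat at sample ``i_peak``.

    Returns ``(apd90_s, t_upstroke, amplitude)``; ``apd90_s`` is NaN when no
    90 %-repolarization crossing occurs before the next beat's upstroke
    (incomplete repolarization).
    """
    seg = slice(i_prev_peak, i_peak + 1)
    i_dia = i_prev_peak + int(np.argmin(vm[seg]))
    v_dia = vm[i_dia]
    v_peak = vm[i_peak]
    # upstroke: max dV/dt between the diastolic minimum and the peak
    up = slice(i_dia, i_peak + 1)
    i_up = i_dia + int(np.argmax(dvdt[up]))
    t_up = t[i_up]
    level = v_peak - 0.9 * (v_peak - v_dia)
    end = i_next_peak if i_next_peak is not None else len(vm) - 1
    below = np.flatnonzero(vm[i_peak:end + 1] < level)
    if below.size == 0 or below[0] == 0:
        return float("nan"), float(t_up), float(v_peak - v_dia)
    k = i_peak + below[0]
    t_cross = _interp_crossing(t[k - 1], vm[k - 1], t[k], vm[k], level)
    return float(t_cross - t_up), float(t_up), float(v_peak - v_dia)


def extract(t: np.ndarray, vm: np.ndarray, dvdt: np.ndarray | None = None,
            prominence: float = PROMINENCE) -> BiomarkerSeries:
    """Full biomarker extraction for one trace.

    ``dvdt`` should be the solver-evaluated derivative trace; when absent it
    is approximated by central differences (grid-dependent, test use only).
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if dvdt is None:
        dvdt = np.gradient(vm, t)
    idx, _ = find_peaks(vm, prominence=prominence)
    flags: list[str] = []
    if idx.size < 2:
        if idx.size == 0:
            flags.append("no_peaks")
        flags.append("too_few_peaks")
        return BiomarkerSeries(np.empty(0), np.empty(0), None, int(idx.size),
                               tuple(flags))
    rr = np.diff(t[idx])
    # complete beats: every peak with a preceding peak (hence a diastolic min)
    n = idx.size - 1
    a90 = np.empty(n)
    t_up = np.empty(n)
    amp = np.empty(n)
    for k in range(n):
        nxt = int(idx[k + 2]) if k + 2 < idx.size else None
        a90[k], t_up[k], amp[k] = apd90(t, vm, dvdt, int(idx[k]), int(idx[k + 1]), nxt)
    beats = BeatMarkers(
        peak_times=t[idx[1:]],
        peak_voltages=vm[idx[1:]],
        upstroke_times=t_up,
        amplitudes=amp,
        apd90=a90,
    )
    if np.any(~np.isfinite(a90)):
        flags.append("incomplete_repolarization")
    if rr.size >= 2 and np.std(rr) > IRREGULAR_CV * np.mean(rr):
        flags.append("irregular")
    return BiomarkerSeries(rr=rr, apd90=a90, beats=beats, n_peaks=int(idx.size),
                           flags=tuple(flags))
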