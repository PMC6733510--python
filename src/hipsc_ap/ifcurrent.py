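"""Exchangeable formulations of the funny current I_f and their voltage-clamp
characterization.

Four single-gate formulations can be hosted in the model's ``Xf`` state slot:

* ``paci`` — the native formulation: lumped reversal at -17 mV, half
  activation near -78 mV, slow sigmoidal time constant (~1.9 s maximum).
* ``severi2012`` — rabbit sinoatrial-node gating: half activation at
  -52.5 mV (strongly active in the diastolic range), fast kinetics, current
  split equally between Na+ and K+ components.
* ``fabbri2017`` — human sinoatrial-node gating with the piecewise
  steady-state activation and the rate-sum time constant of that model;
  Na:K split chosen to give the published ~ -22 mV reversal under the host's
  ionic conditions.
* ``koivumaki2018`` — a reconstruction calibrated to human embryonic stem
  cell-derived cardiomyocyte voltage-clamp data (half activation -96.9 mV,
  slope 8.8 mV, bell-shaped time constant peaking near -90 mV, HCN-style
  Na:K split).  The source publication's exact coefficients were not
  available when this module was written; gating values are documented
  reconstructions, adequate for the qualitative comparisons made here.

Substituting a formulation changes only the gating equations and current
equation; membrane capacitance, g_f and all ionic concentrations of the host
model are untouched, so the virtual channel density is identical across
variants.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels
from ._layout import IF_IDS
from .parameters import ModelParameters, load_parameters

__all__ = [
    "IfFormulation",
    "FORMULATIONS",
    "get_formulation",
    "substitute_if",
    "VoltageClampProtocol",
    "ClampStep",
    "run_voltage_clamp",
    "if_steady_state",
    "if_time_constant",
    "if_current_value",
]


@dataclasses.dataclass(frozen=True)
class IfFormulation:
    """Metadata of one funny-current formulation (single activation gate)."""

    identifier: str
    n_gates: int = 1
    splits_na_k: bool = True

    @property
    def if_id(self) -> int:
        return IF_IDS[self.identifier]


FORMULATIONS: dict[str, IfFormulation] = {
    "paci": IfFormulation("paci", splits_na_k=False),
    "severi2012": IfFormulation("severi2012"),
    "fabbri2017": IfFormulation("fabbri2017"),
    "koivumaki2018": IfFormulation("koivumaki2018"),
}


def get_formulation(name: str) -> IfFormulation:
    try:
        return FORMULATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown I_f formulation {name!r}; available: {sorted(FORMULATIONS)}"
        ) from None


def if_steady_state(name: str, vm: np.ndarray) -> np.ndarray:
    """Steady-state activation over membrane potential ``vm`` (V)."""
    ifid = get_formulation(name).if_id
    vm = np.atleast_1d(np.asarray(vm, dtype=float))
    return np.array([_kernels.if_gate(v * 1000.0, ifid)[0] for v in vm])


def if_time_constant(name: str, vm: np.ndarray) -> np.ndarray:
    """Activation time constant (s) over membrane potential ``vm`` (V)."""
    ifid = get_formulation(name).if_id
    vm = np.atleast_1d(np.asarray(vm, dtype=float))
    return np.array([_kernels.if_gate(v * 1000.0, ifid)[1] for v in vm])


def if_current_value(name: str, gate: float, vm: float,
                     params: ModelParameters, nai: float | None = None) -> float:
    """Current density (A/F) at one gate value and potential.

    ``nai`` overrides the cytosolic Na+ used for the Na+ reversal (the blank
    clamp host holds it fixed); defaults to the variant's published initial
    value.
    """
    form = get_formulation(name)
    if not 0.0 <= gate <= 1.0:
        raise ValueError("gate state must lie in [0, 1]")
    if nai is None:
        _, y0 = load_parameters(params.variant)
        nai = float(y0[17])
    rtf = params.R * params.T / params.F
    e_na = rtf * np.log(params.Nao / nai)
    e_k = rtf * np.log(params.Ko / params.Ki)
    from ._layout import VARIANT_IDS

    total, _ = _kernels.if_current(vm, gate, e_na, e_k, params.gf, params.E_f,
                                   params.fNaIf, form.if_id,
                                   VARIANT_IDS[params.variant], params.Ko)
    return float(total)


def substitute_if(params: ModelParameters, formulation: str | IfFormulation) -> ModelParameters:
    """Host model with the funny current replaced by another formulation.

    Only the gating/current equations change; ``gf``, capacitance and all
    ionic concentrations are those of the host.
    """
    name = formulation.identifier if isinstance(formulation, IfFormulation) else formulation
    get_formulation(name)
    return params.replace(if_formulation=name)


@dataclasses.dataclass(frozen=True)
class VoltageClampProtocol:
    """Holding potential, hyperpolarizing steps, and durations (SI units)."""

    holding_potential: float = -0.040
    step_potentials: tuple[float, ...] = (-0.050, -0.060, -0.070, -0.080, -0.090, -0.100)
    step_duration: float = 5.0
    tail_duration: float = 5.0

    def __post_init__(self) -> None:
        if self.step_duration <= 0 or self.tail_duration <= 0:
            raise ValueError("durations must be > 0")
        for v in (self.holding_potential, *self.step_potentials):
            if not -0.2 <= v <= 0.1:
                raise ValueError(f"clamp potential {v} V outside [-0.2, 0.1] V")


@dataclasses.dataclass
class ClampStep:
    """Current trace of one clamp step (step + tail), Vm clamped exactly."""

    step_potential: float
    t: np.ndarray
    Vm: np.ndarray
    current: np.ndarray
    gate: np.ndarray


def run_voltage_clamp(
    formulation: str | IfFormulation,
    protocol: VoltageClampProtocol = VoltageClampProtocol(),
    params: ModelParameters | None = None,
    output_step: float = 1e-3,
) -> list[ClampStep]:
    """Simulated voltage clamp of I_f in the blank cellular host.

    The host contributes only its capacitance, g_f and fixed ionic
    concentrations (held at the Paci2018 initial values — the clamp is a
    channel characterization, not a cell simulation).  With Vm piecewise
    constant the single activation gate relaxes exactly exponentially, so
    the gate trajectory is evaluated in closed form:
    x(t) = x_inf + (x0 - x_inf) exp(-t / tau).
    """
    name = formulation.identifier if isinstance(formulation, IfFormulation) else formulation
    form = get_formulation(name)
    if params is None:
        params, _ = load_parameters("paci2018")
    _, y0 = load_parameters(params.variant)
    nai = float(y0[17])
    rtf = params.R * params.T / params.F
    e_na = rtf * np.log(params.Nao / nai)
    e_k = rtf * np.log(params.Ko / params.Ki)

    hold_inf, _ = _kernels.if_gate(protocol.holding_potential * 1000.0, form.if_id)

    results = []
    for v_step in protocol.step_potentials:
        segs_t, segs_v, segs_x = [], [], []
        x0 = hold_inf
        t_off = 0.0
        for v_seg, dur in ((v_step, protocol.step_duration),
                           (protocol.holding_potential, protocol.tail_duration)):
            xinf, tau = _kernels.if_gate(v_seg * 1000.0, form.if_id)
            tloc = np.arange(0.0, dur + 0.5 * output_step, output_step)
            x = xinf + (x0 - xinf) * np.exp(-tloc / tau)
            segs_t.append(tloc + t_off)
            segs_v.append(np.full_like(tloc, v_seg))
            segs_x.append(x)
            x0 = x[-1]
            t_off += dur
        t = np.concatenate(segs_t)
        vm = np.concatenate(segs_v)
        gate = np.concatenate(segs_x)
        from ._layout import VARIANT_IDS

        variant_id = VARIANT_IDS[params.variant]
        cur = np.array([
            _kernels.if_current(v, g, e_na, e_k, params.gf, params.E_f,
                                params.fNaIf, form.if_id, variant_id,
                                params.Ko)[0]
            for v, g in zip(vm, gate)
        ])
        results.append(ClampStep(step_potential=v_step, t=t, Vm=vm,
                                 current=cur, gate=gate))
    return results


def clamp_to_frame(formulation: str, steps: list[ClampStep]):
    """Tidy CSV-ready table (formulation, step_mV, time_s, current_ApF)."""
    import pandas as pd

    frames = []
    for s in steps:
        frames.append(pd.DataFrame({
            "formulation": formulation,
            "step_mV": round(s.step_potential * 1000.0, 3),
            "time_s": s.t,
            "current_ApF": s.current,
        }))
    return pd.concat(frames, ignore_index=True)
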