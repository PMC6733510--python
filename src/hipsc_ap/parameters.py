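"""Model parameter sets and state vectors for the hiPSC-CM variants.

Parameter values are shipped as human-readable YAML files (one per variant,
see ``hipsc_ap/data``) and loaded into an immutable :class:`ModelParameters`.
The packed :func:`ModelParameters.pack` array is what the compiled kernels
consume; its slot order is defined in :mod:`hipsc_ap._layout`.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import yaml

from ._layout import (
    CONC_SLOTS,
    GATE_SLOTS,
    IDX,
    IF_ID_NAMES,
    IF_IDS,
    NPARAMS,
    NSTATES,
    P,
    PARAM_NAMES,
    SCALABLE,
    STATE_NAMES,
    VARIANT_IDS,
)

__all__ = [
    "ModelParameters",
    "load_parameters",
    "state_from_dict",
    "state_to_dict",
    "validate_state",
    "GATE_TOLERANCE",
]

#: gates may stray this far outside [0, 1] before a run is rejected
GATE_TOLERANCE = 1e-6


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Immutable parameter set of one model variant.

    ``variant`` selects the right-hand side ("paci2017" or "paci2018") and
    ``if_formulation`` the funny-current equations hosted in the ``Xf`` state
    slot.  All other fields are physical parameters in SI units (V, s, mM;
    conductances in S/F).
    """

    variant: str
    if_formulation: str = "paci"
    values: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_IDS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of "
                f"{sorted(VARIANT_IDS)}"
            )
        if self.if_formulation not in IF_IDS:
            raise ValueError(
                f"unknown I_f formulation {self.if_formulation!r}; expected "
                f"one of {sorted(IF_IDS)}"
            )
        missing = [n for n in PARAM_NAMES[:-2] if n not in self.values]
        if missing:
            raise ValueError(f"missing parameter fields: {missing}")
        self._validate()

    def _validate(self) -> None:
        v = self.values
        for name in SCALABLE:
            if v[name] < 0:
                raise ValueError(f"conductance {name} must be >= 0, got {v[name]}")
        if v["Cm"] <= 0 or v["Vc"] <= 0 or v["V_SR"] <= 0:
            raise ValueError("capacitance and volumes must be positive")
        for name in ("Nao", "Ko", "Cao", "Ki"):
            if v[name] <= 0:
                raise ValueError(f"external concentration {name} must be > 0")

    def __getattr__(self, name: str):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    def replace(self, **updates: float) -> "ModelParameters":
        """Return a copy with the given parameter fields replaced."""
        meta = {k: updates.pop(k) for k in ("variant", "if_formulation") if k in updates}
        unknown = [k for k in updates if k not in self.values]
        if unknown:
            raise KeyError(f"unknown parameter fields: {unknown}")
        values = {**self.values, **updates}
        return ModelParameters(
            variant=meta.get("variant", self.variant),
            if_formulation=meta.get("if_formulation", self.if_formulation),
            values=values,
        )

    def pack(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the kernels."""
        p = np.empty(NPARAMS, dtype=np.float64)
        for name, i in P.items():
            if name == "variant_id":
                p[i] = VARIANT_IDS[self.variant]
            elif name == "if_id":
                p[i] = IF_IDS[self.if_formulation]
            else:
                p[i] = self.values[name]
        return p

    @classmethod
    def from_packed(cls, p: np.ndarray) -> "ModelParameters":
        values = {n: float(p[i]) for n, i in P.items() if n not in ("variant_id", "if_id")}
        variant = {v: k for k, v in VARIANT_IDS.items()}[int(p[P["variant_id"]])]
        return cls(variant=variant, if_formulation=IF_ID_NAMES[int(p[P["if_id"]])], values=values)


def _data_text(name: str) -> str:
    return resources.files("hipsc_ap.data").joinpath(name).read_text()


def load_parameters(variant: str) -> tuple[ModelParameters, np.ndarray]:
    """Load a variant's published parameter set and initial state.

    Returns ``(params, initial_state)`` where the state follows the canonical
    23-slot layout of :data:`hipsc_ap._layout.STATE_NAMES`.
    """
    if variant not in VARIANT_IDS:
        raise ValueError(f"unknown variant {variant!r}")
    doc = yaml.safe_load(_data_text(f"{variant}.yaml"))
    params = ModelParameters(variant=doc["variant"], values=dict(doc["parameters"]))
    state = state_from_dict(doc["initial_state"])
    return params, state


def state_from_dict(d: dict[str, float]) -> np.ndarray:
    missing = [n for n in STATE_NAMES if n not in d]
    if missing:
        raise ValueError(f"missing state fields: {missing}")
    return np.array([float(d[n]) for n in STATE_NAMES], dtype=np.float64)


def state_to_dict(y: np.ndarray) -> dict[str, float]:
    return {n: float(y[IDX[n]]) for n in STATE_NAMES}


def validate_state(y: np.ndarray, *, clip: bool = False) -> np.ndarray:
    """Check state invariants; optionally return a reporting copy with gates
    clipped to [0, 1].

    Raises ``ValueError`` when a gate strays beyond :data:`GATE_TOLERANCE`
    outside the unit interval, a concentration is non-positive, or the
    membrane potential leaves the physiological window [-0.2, 0.1] V.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (NSTATES,):
        raise ValueError(f"state must have shape ({NSTATES},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state entries")
    gates = y[list(GATE_SLOTS)]
    if gates.min() < -GATE_TOLERANCE or gates.max() > 1 + GATE_TOLERANCE:
        bad = [STATE_NAMES[s] for s in GATE_SLOTS
               if y[s] < -GATE_TOLERANCE or y[s] > 1 + GATE_TOLERANCE]
        raise ValueError(f"gating variables out of [0,1]: {bad}")
    if np.any(y[list(CONC_SLOTS)] <= 0):
        raise ValueError("non-positive ion concentration")
    if not (-0.2 <= y[IDX["Vm"]] <= 0.1):
        raise ValueError(f"Vm out of range: {y[IDX['Vm']]} V")
    if clip:
        y = y.copy()
        for s in GATE_SLOTS:
            y[s] = min(1.0, max(0.0, y[s]))
    return y
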