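"""Canonical packed layouts shared by the Python API and the compiled kernels.

The two model variants share a single 23-slot state vector; slots that a
variant does not use (the 2013-style SR release gate ``g`` for Paci2018, the
RyR gating states for Paci2017) are frozen at their initial value with zero
derivative.  Keeping one layout lets the funny-current formulation be swapped
without changing the state dimension (all four formulations are single-gate,
hosted in the ``Xf`` slot).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# State vector slots
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "Vm",      # membrane potential, V
    "Ca_SR",   # sarcoplasmic-reticulum Ca2+, mM
    "Cai",     # cytosolic Ca2+, mM
    "g",       # 2013-style SR release gate (Paci2017 only)
    "d",       # ICaL activation
    "f1",      # ICaL voltage inactivation (slow)
    "f2",      # ICaL voltage inactivation (fast)
    "fCa",     # ICaL Ca-dependent inactivation
    "Xr1",     # IKr activation
    "Xr2",     # IKr inactivation
    "Xs",      # IKs activation
    "h",       # INa fast inactivation
    "j",       # INa slow inactivation
    "m",       # INa activation
    "Xf",      # funny-current activation (any formulation)
    "q",       # Ito inactivation
    "r",       # Ito activation
    "Nai",     # cytosolic Na+, mM
    "mL",      # INaL activation
    "hL",      # INaL inactivation
    "RyRa",    # RyR adaptation (Paci2018 only)
    "RyRo",    # RyR open gate (Paci2018 only)
    "RyRc",    # RyR closed/refractory gate (Paci2018 only)
)
NSTATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: state slots that are dimensionless gates constrained to [0, 1]
GATE_NAMES = (
    "g", "d", "f1", "f2", "fCa", "Xr1", "Xr2", "Xs", "h", "j", "m", "Xf",
    "q", "r", "mL", "hL", "RyRa", "RyRo", "RyRc",
)
GATE_SLOTS = tuple(IDX[n] for n in GATE_NAMES)

#: state slots holding ion concentrations (strictly positive, mM)
CONC_NAMES = ("Ca_SR", "Cai", "Nai")
CONC_SLOTS = tuple(IDX[n] for n in CONC_NAMES)

# ---------------------------------------------------------------------------
# Membrane currents, A/F, in kernel output order
# ---------------------------------------------------------------------------
CURRENT_NAMES = (
    "INa", "INaL", "ICaL", "Ito", "IKr", "IKs", "IK1", "If",
    "INaCa", "INaK", "IpCa", "IbNa", "IbCa",
)
NCURRENTS = len(CURRENT_NAMES)
CUR = {name: i for i, name in enumerate(CURRENT_NAMES)}

# ---------------------------------------------------------------------------
# Packed parameter vector slots
# ---------------------------------------------------------------------------
PARAM_NAMES = (
    # physical constants
    "F", "R", "T",
    # geometry
    "Cm", "Vc", "V_SR",
    # fixed ion concentrations, mM
    "Nao", "Ko", "Cao", "Ki",
    # maximal conductances / permeabilities
    "gNa", "gNaL", "gCaL", "gto", "gKr", "gKs", "gK1", "gf",
    "gPCa", "gbNa", "gbCa",
    # NCX
    "kNaCa", "KmCa", "KmNai", "Ksat", "gamma", "alphaNaCa",
    # NaK pump
    "PNaK", "KmK", "KmNa",
    # sarcolemmal Ca pump
    "KPCa",
    # funny current
    "E_f", "fNaIf",
    # SR uptake / leak
    "VmaxUp", "Kup", "V_leak",
    # 2013-style release (Paci2017)
    "a_rel", "b_rel", "c_rel",
    # RyR release (Paci2018)
    "g_irel_max", "RyRa1", "RyRa2", "RyRahalf", "RyRohalf", "RyRchalf",
    # Ca buffering
    "Buf_C", "Kbuf_C", "Buf_SR", "Kbuf_SR",
    # IKr activation V1/2 constants
    "L0", "Q",
    # IKs Na permeability ratio
    "PkNa",
    # INaL inactivation
    "Vh_hLate", "tau_hLate",
    # discrete switches (stored as floats, read as ints in kernels)
    "variant_id", "if_id",
)
NPARAMS = len(PARAM_NAMES)
P = {name: i for i, name in enumerate(PARAM_NAMES)}

VARIANT_IDS = {"paci2017": 0, "paci2018": 1}
IF_IDS = {"paci": 0, "severi2012": 1, "fabbri2017": 2, "koivumaki2018": 3}
IF_ID_NAMES = {v: k for k, v in IF_IDS.items()}

#: parameter fields that conductance scalings may target
SCALABLE = (
    "gNa", "gNaL", "gCaL", "gto", "gKr", "gKs", "gK1", "gf",
    "gPCa", "gbNa", "gbCa", "kNaCa", "PNaK",
)
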