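"""Model core: transcription oracle, current consistency, integration contract."""

from __future__ import annotations

import numpy as np
import pytest

from hipsc_ap._layout import IDX, STATE_NAMES
from hipsc_ap.model import advance, compute_currents, derivatives, integrate
from hipsc_ap.parameters import state_to_dict, validate_state
from hipsc_ap.pharmacology import apply_scaling

from ._oracle import derivatives as oracle_derivatives


def _rel_close(a, b, rtol=1e-9, atol=1e-13):
    return np.all(np.abs(a - b) <= rtol * np.maximum(np.abs(a), np.abs(b)) + atol)


@pytest.mark.parametrize("variant", ["paci2017", "paci2018"])
def test_independent_transcription_oracle(variant, paci2017, paci2018,
                                          random_state_batch):
    """The packaged right-hand side agrees with a second, independently coded
    transcription of the same equations at random physiological states."""
    params, _ = {"paci2017": paci2017, "paci2018": paci2018}[variant]
    for y in random_state_batch:
        mine = derivatives(y, params)
        ref = oracle_derivatives(state_to_dict(y), params.values, variant, "paci")
        ref_vec = np.array([ref[n] for n in STATE_NAMES])
        assert _rel_close(mine, ref_vec), (
            f"max rel err {np.max(np.abs(mine - ref_vec) / (np.abs(ref_vec) + 1e-30))}"
        )


@pytest.mark.parametrize("formulation", ["severi2012", "fabbri2017", "koivumaki2018"])
def test_oracle_covers_substituted_formulations(formulation, paci2018,
                                                random_state_batch):
    from hipsc_ap.ifcurrent import substitute_if

    params, _ = paci2018
    sub = substitute_if(params, formulation)
    for y in random_state_batch[:4]:
        mine = derivatives(y, sub)
        ref = oracle_derivatives(state_to_dict(y), sub.values, "paci2018", formulation)
        ref_vec = np.array([ref[n] for n in STATE_NAMES])
        assert _rel_close(mine, ref_vec)


def test_current_sum_matches_vm_derivative(paci2018, paci2017):
    """-(sum of currents) equals the Vm component of the derivative at machine
    precision (same code path by construction, asserted at 100 states)."""
    from .conftest import random_states

    for params, _ in (paci2018, paci2017):
        for y in random_states(50, seed=4):
            cur = compute_currents(y, params)
            dvm = derivatives(y, params)[IDX["Vm"]]
            total = sum(cur.values())
            assert abs(-total - dvm) <= 1e-12 * max(1.0, abs(total))


def test_zero_conductance_zeroes_current(paci2018, random_state_batch):
    params, _ = paci2018
    y = random_state_batch[0]
    for scale_name, current_name in [("gNa", "INa"), ("gCaL", "ICaL"),
                                     ("gKr", "IKr"), ("gf", "If"),
                                     ("gNaL", "INaL"), ("gKs", "IKs")]:
        blocked = apply_scaling(params, {scale_name: 0.0})
        assert compute_currents(y, blocked)[current_name] == 0.0


def test_published_initial_conditions_are_not_equilibrium(paci2018, paci2017):
    """The models are spontaneous: dVm/dt is finite and nonzero at the
    published initial conditions."""
    for params, y0 in (paci2018, paci2017):
        dvm = derivatives(y0, params)[IDX["Vm"]]
        assert np.isfinite(dvm) and dvm != 0.0


def test_gating_steady_state_has_zero_gate_derivative(paci2018):
    """Setting every voltage gate to its steady state at clamped Vm zeroes
    its derivative (steady-state definition).  The gate equations are linear
    in the gate, so the fixed point is extracted exactly from two derivative
    evaluations: x_inf = dx(0) / (dx(0) - dx(1))."""
    params, y0 = paci2018
    # f1/fCa are excluded: their time constants depend on the gate itself
    # (Ca-conditional factors), so the two-point extraction is not exact
    gates = ("d", "f2", "Xr1", "Xr2", "Xs", "h", "j", "m", "Xf",
             "q", "r", "mL", "hL")
    y = y0.copy()
    for name in gates:
        i = IDX[name]
        y0g = y.copy(); y0g[i] = 0.0
        y1g = y.copy(); y1g[i] = 1.0
        d0 = derivatives(y0g, params)[i]
        d1 = derivatives(y1g, params)[i]
        y[i] = d0 / (d0 - d1)
    dy = derivatives(y, params)
    for name in gates:
        assert abs(dy[IDX[name]]) < 1e-9 * max(1.0, abs(dy[IDX["Vm"]]))


def test_spontaneous_beating_baseline(paci2018):
    """Paci2018 produces repeated spontaneous APs (no stimulus anywhere)."""
    params, y0 = paci2018
    res = integrate(y0, params, 30.0)
    assert res.ok
    from hipsc_ap.biomarkers import detect_peaks

    times, volts = detect_peaks(res.t, res.Vm)
    assert times.size >= 5
    assert volts.max() > 0.0  # overshooting APs
    assert res.Vm.min() < -0.065  # diastolic potential


def test_restart_invariance(paci2018):
    """Splitting a run and restarting from the saved state reproduces the
    continuous run; agreement is solver-tolerance limited, so it is checked
    at tight tolerance over a window away from the sensitive upstrokes."""
    params, y0 = paci2018
    kw = dict(rtol=1e-9, atol=1e-11)
    full = integrate(y0, params, 6.0, **kw)
    first = integrate(y0, params, 3.0, **kw)
    second = integrate(first.final_state, params, 3.0, t0=3.0, **kw)
    overlap = full.Vm[full.t > 3.0]
    np.testing.assert_allclose(second.Vm[1:], overlap, atol=1e-6)


def test_unit_scaling_is_bit_identical(paci2018):
    params, y0 = paci2018
    unit = apply_scaling(params, {"gNa": 1.0, "gCaL": 1.0, "gKr": 1.0, "gf": 1.0})
    a = integrate(y0, params, 2.0)
    b = integrate(y0, unit, 2.0)
    np.testing.assert_array_equal(a.Vm, b.Vm)


def test_tolerance_robustness_of_rr(paci2018):
    """Tightening solver tolerances tenfold moves the mean rr by < 0.1 %."""
    params, y0 = paci2018
    rrs = []
    for rtol, atol in ((1e-7, 1e-9), (1e-8, 1e-10)):
        state, _ = advance(y0, params, 60.0, rtol=rtol, atol=atol)
        res = integrate(state, params, 40.0, rtol=rtol, atol=atol)
        from hipsc_ap.biomarkers import extract

        rrs.append(extract(res.t, res.Vm, res.dVmdt).mean_rr)
    assert abs(rrs[0] - rrs[1]) / rrs[1] < 1e-3


def test_result_invariants(paci2018):
    params, y0 = paci2018
    res = integrate(y0, params, 5.0, with_currents=True)
    assert np.all(np.diff(res.t) > 0)
    assert res.Vm.shape == res.t.shape == res.dVmdt.shape
    assert res.currents.shape == (res.t.size, 13)
    validate_state(res.final_state)
    assert res.stats["nfev"] > 0


def test_invalid_inputs_rejected(paci2018):
    params, y0 = paci2018
    with pytest.raises(ValueError):
        integrate(y0, params, -1.0)
    with pytest.raises(ValueError):
        integrate(y0, params, 1.0, output_step=0.0)
    bad = y0.copy()
    bad[IDX["h"]] = 1.5
    with pytest.raises(ValueError):
        validate_state(bad)
    bad = y0.copy()
    bad[IDX["Cai"]] = -1e-6
    with pytest.raises(ValueError):
        validate_state(bad)


def test_export_roundtrip(tmp_path, paci2018):
    import pandas as pd

    params, y0 = paci2018
    res = integrate(y0, params, 1.0, with_currents=True)
    df = res.to_frame()
    path = tmp_path / "trace.csv"
    df.to_csv(path, index=False)
    back = pd.read_csv(path)
    np.testing.assert_allclose(back["Vm_V"].to_numpy(), res.Vm, rtol=1e-12)
    assert "IKr_ApF" in back.columns
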