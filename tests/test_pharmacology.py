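"""Hill-equation pharmacology: printed-table reproduction and properties."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipsc_ap.parameters import load_parameters
from hipsc_ap.pharmacology import (
    CompoundProfile,
    HillInhibition,
    apply_scaling,
    build_scaling,
    build_scaling_at_concentration,
    concentration_for_fraction,
    gf_sweep_factors,
    hill_fraction,
    load_compound_profiles,
    profile_grid,
)


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


# Printed scale-factor tables for the three compound profiles.  The first two
# are driven by primary-target set points (concentration derived), the third
# by the shared concentration series (all factors derived).
DILTIAZEM_CELLS = [
    # (primary gCaL fraction, printed concentration, printed gKr, printed gNa)
    (0.05, "10.1", "0.58", "0.74"),
    (0.1, "5.22", "0.75", "0.87"),
    (0.5, "0.76", "0.96", "0.987"),
    (0.9, "0.111", "0.996", "0.999"),
]
MOXI_II_CELLS = [
    # (primary gKr fraction, printed concentration, printed gCaL, printed gNa)
    (0.25, "277.4", "0.38", "0.80"),
    (0.5, "86.2", "0.67", "0.93"),
    (0.9, "8.32", "0.95", "0.993"),
    (0.95, "3.76", "0.979", "0.997"),
]
MOXI_III_CELLS = [
    # (concentration uM, printed gKr, printed gNaL, printed gKs)
    (277.4, "0.34", "0.59", "0.15"),
    (86.2, "0.51", "0.84", "0.37"),
    (8.32, "0.81", "0.985", "0.86"),
    (3.76, "0.87", "0.994", "0.930"),
]


@pytest.mark.parametrize("fraction,conc,gkr,gna", DILTIAZEM_CELLS)
def test_diltiazem_table_cells(fraction, conc, gkr, gna):
    """Every printed Diltiazem cell is reproduced at its printed precision."""
    profile, _ = profile_grid("diltiazem_I")
    scaling, c = build_scaling(profile, fraction)
    assert _round_half_away(c, _decimals(conc)) == pytest.approx(float(conc))
    assert _round_half_away(scaling["gKr"], _decimals(gkr)) == pytest.approx(float(gkr))
    assert _round_half_away(scaling["gNa"], _decimals(gna)) == pytest.approx(float(gna))


@pytest.mark.parametrize("fraction,conc,gcal,gna", MOXI_II_CELLS)
def test_moxifloxacin_ii_table_cells(fraction, conc, gcal, gna):
    profile, _ = profile_grid("moxifloxacin_II")
    scaling, c = build_scaling(profile, fraction)
    assert _round_half_away(c, _decimals(conc)) == pytest.approx(float(conc))
    assert _round_half_away(scaling["gCaL"], _decimals(gcal)) == pytest.approx(float(gcal))
    assert _round_half_away(scaling["gNa"], _decimals(gna)) == pytest.approx(float(gna))


@pytest.mark.parametrize("conc,gkr,gnal,gks", MOXI_III_CELLS)
def test_moxifloxacin_iii_table_cells(conc, gkr, gnal, gks):
    """The alternative profile's cells are forward evaluations at the shared
    concentration series (its printed primary column is itself rounded)."""
    profile, _ = profile_grid("moxifloxacin_III")
    scaling = build_scaling_at_concentration(profile, conc)
    assert _round_half_away(scaling["gKr"], _decimals(gkr)) == pytest.approx(float(gkr))
    assert _round_half_away(scaling["gNaL"], _decimals(gnal)) == pytest.approx(float(gnal))
    assert _round_half_away(scaling["gKs"], _decimals(gks)) == pytest.approx(float(gks))


def test_half_maximum_identity():
    for slope in (0.5, 1.0, 1.14, 2.3):
        inh = HillInhibition("gKr", 13.2, slope)
        assert hill_fraction(13.2, inh) == pytest.approx(0.5, abs=1e-15)
        assert concentration_for_fraction(0.5, inh) == pytest.approx(13.2, rel=1e-14)


def test_zero_concentration_leaves_channel_untouched():
    inh = HillInhibition("gNa", 22.4, 1.29)
    assert hill_fraction(0.0, inh) == 1.0


@settings(deadline=None, derandomize=True, max_examples=80)
@given(
    c=st.floats(1e-4, 1e4),
    ic50=st.floats(1e-3, 1e3),
    slope=st.floats(0.2, 4.0),
)
def test_hill_monotone_and_invertible(c, ic50, slope):
    """s(C) is strictly decreasing in C, increasing in IC50, and the inverse
    round-trips to 1e-12 relative."""
    inh = HillInhibition("gKr", ic50, slope)
    s = hill_fraction(c, inh)
    assert 0.0 < s < 1.0
    assert hill_fraction(c * 1.01, inh) < s
    assert hill_fraction(c, HillInhibition("gKr", ic50 * 1.01, slope)) > s
    # the 1e-12 round-trip holds where 1/s - 1 does not cancel catastrophically;
    # far outside the active range the bound is set by float cancellation
    rel = 1e-12 if 0.05 <= c / ic50 <= 20.0 else 1e-8
    assert concentration_for_fraction(s, inh) == pytest.approx(c, rel=rel)
    assert hill_fraction(concentration_for_fraction(s, inh), inh) == pytest.approx(
        s, rel=rel)


def test_domain_errors():
    inh = HillInhibition("gKr", 1.0, 1.0)
    with pytest.raises(ValueError):
        hill_fraction(-0.1, inh)
    for bad in (0.0, 1.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            concentration_for_fraction(bad, inh)
    with pytest.raises(ValueError):
        HillInhibition("gKr", -1.0, 1.0)
    with pytest.raises(ValueError):
        HillInhibition("gKr", 1.0, 0.0)


def test_gf_sweep_factors_exact_set():
    factors = gf_sweep_factors()
    assert factors == [0.0, 0.5, 0.9, 0.99, 1.01, 1.1, 1.5, 2.0, 3.0, 4.0]
    assert len(factors) == 10
    assert 0.0 in factors
    assert 0.99 in factors and 1.01 in factors


def test_degenerate_profile_touches_one_conductance():
    profile = CompoundProfile("X", HillInhibition("gKr", 1.0, 1.0))
    scaling, conc = build_scaling(profile, 0.5)
    assert set(scaling) == {"gKr"}
    assert conc == pytest.approx(1.0)


def test_duplicate_or_unknown_targets_rejected():
    with pytest.raises(ValueError):
        CompoundProfile("X", HillInhibition("gKr", 1.0, 1.0),
                        (HillInhibition("gKr", 2.0, 1.0),))
    with pytest.raises(ValueError):
        CompoundProfile("X", HillInhibition("gWhat", 1.0, 1.0))


def test_apply_scaling_identity_and_zero(paci2018):
    params, _ = paci2018
    same = apply_scaling(params, {})
    assert np.array_equal(same.pack(), params.pack())
    unit = apply_scaling(params, {name: 1.0 for name in ("gNa", "gKr", "gf")})
    assert np.array_equal(unit.pack(), params.pack())
    nogf = apply_scaling(params, {"gf": 0.0})
    assert nogf.gf == 0.0
    assert nogf.gKr == params.gKr


def test_apply_scaling_unknown_target_lists_valid_names(paci2018):
    params, _ = paci2018
    with pytest.raises(KeyError) as err:
        apply_scaling(params, {"gNope": 0.5})
    assert "gCaL" in str(err.value)


def test_diltiazem_half_block_row_matches_table(paci2018):
    """The applied parameter set carries the Table row for half gCaL block."""
    params, _ = paci2018
    profile, _ = profile_grid("diltiazem_I")
    scaling, _ = build_scaling(profile, 0.5)
    scaled = apply_scaling(params, scaling)
    assert scaled.gCaL == pytest.approx(params.gCaL * 0.5, rel=1e-12)
    assert scaled.gKr / params.gKr == pytest.approx(0.96, abs=5e-3)
    assert scaled.gNa / params.gNa == pytest.approx(0.987, abs=5e-4)


def test_shipped_profiles_load():
    profiles = load_compound_profiles()
    assert isinstance(profiles["diltiazem_I"], CompoundProfile)
    assert profiles["moxifloxacin_II"].primary.target == "gKr"
    assert profiles["moxifloxacin_III"].provenance == "Moxifloxacin III"
    # the two gf-only compounds carry no Hill terms
    assert profiles["ivabradine"]["gf_scaling_only"]
    assert profiles["forskolin"]["direction"] == "augmentation"
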