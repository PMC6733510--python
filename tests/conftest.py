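"""Shared fixtures: parameter sets and random physiological states."""

from __future__ import annotations

import numpy as np
import pytest

from hipsc_ap._layout import IDX, NSTATES, STATE_NAMES
from hipsc_ap.parameters import load_parameters


@pytest.fixture(scope="session")
def paci2018():
    return load_parameters("paci2018")


@pytest.fixture(scope="session")
def paci2017():
    return load_parameters("paci2017")


def random_states(n: int, seed: int) -> np.ndarray:
    """Random state vectors inside the physiological invariant region."""
    rng = np.random.default_rng(seed)
    ys = np.empty((n, NSTATES))
    for k in range(n):
        y = np.empty(NSTATES)
        y[IDX["Vm"]] = rng.uniform(-0.09, 0.04)
        y[IDX["Ca_SR"]] = rng.uniform(0.05, 0.6)
        y[IDX["Cai"]] = rng.uniform(1e-5, 1e-3)
        y[IDX["Nai"]] = rng.uniform(5.0, 15.0)
        for name in STATE_NAMES:
            i = IDX[name]
            if name not in ("Vm", "Ca_SR", "Cai", "Nai"):
                y[i] = rng.uniform(0.0, 1.0)
        ys[k] = y
    return ys


@pytest.fixture(scope="session")
def random_state_batch():
    return random_states(10, seed=20230917)
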