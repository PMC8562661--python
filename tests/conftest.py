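"""Shared fixtures: thaumatin presets and a small simulated dataset."""

import numpy as np
import pytest

from pinksfx import beam, presets, simulate, truth
from pinksfx.geometry import SymmetrySpec, UnitCell


@pytest.fixture(scope="session")
def thaumatin_cell() -> UnitCell:
    return presets.THAUMATIN_CELL


@pytest.fixture(scope="session")
def p41212() -> SymmetrySpec:
    return SymmetrySpec.from_symbol("P41212")


@pytest.fixture(scope="session")
def p1() -> SymmetrySpec:
    return SymmetrySpec.from_symbol("P1")


@pytest.fixture(scope="session")
def truth_set(thaumatin_cell, p41212):
    """Thaumatin-like ground truth to 2.5 A with a 2% Bijvoet ratio."""
    return truth.generate_structure_factors(
        thaumatin_cell, p41212, d_min=2.5, wilson_b=20.0,
        target_bijvoet_ratio=0.02, seed=101,
    )


def cc_null_bound(x, y, n_sigma=3.0):
    """Null-hypothesis band for a Pearson correlation of independent series.

    Delta-method standard error, valid for heavy-tailed data where 1/sqrt(n)
    underestimates the estimator spread: Var(r) ~ sum(x^2 y^2) / (sum x^2 *
    sum y^2) for centred, independent x and y.
    """
    x = np.asarray(x) - np.mean(x)
    y = np.asarray(y) - np.mean(y)
    se = np.sqrt(np.sum(x**2 * y**2)) / np.sqrt(np.sum(x**2) * np.sum(y**2))
    return n_sigma * se


def make_dataset(truth_set, cell, sym, spectrum_id, n_patterns, seed, **cfg_kwargs):
    cfg = simulate.SimConfig(n_patterns=n_patterns, seed=seed, **cfg_kwargs)
    sim = simulate.StillSimulator(
        truth_set, cell, sym, presets.spectrum(spectrum_id),
        presets.DEFAULT_PROFILE, presets.JUNGFRAU_16M, cfg, spectrum_id,
    )
    return sim.simulate_dataset()


@pytest.fixture(scope="session")
def small_pink_dataset(truth_set, thaumatin_cell, p41212):
    """60 pink-beam patterns; enough for merge plumbing tests."""
    return make_dataset(truth_set, thaumatin_cell, p41212, "pink-6keV", 60, seed=7)


@pytest.fixture(scope="session")
def small_sase_dataset(truth_set, thaumatin_cell, p41212):
    return make_dataset(truth_set, thaumatin_cell, p41212, "sase-6keV", 60, seed=7)
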