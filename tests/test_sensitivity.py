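import numpy as np
import pytest

from mirclock.model import FLUX_IDS
from mirclock.parameters import SENSITIVITY_PARAMS
from mirclock.sensitivity import (
    _column,
    cycle_averaged_fluxes,
    flux_sensitivity,
    parameter_flux_reachability,
    sensitivity_matrix,
    significance_counts,
    static_flux_sensitivity,
)


def test_reachability_structure():
    r = parameter_flux_reachability()
    assert r.shape == (49, 76)
    # terminal-species constants only move their own flux
    assert list(r.index[r["C4"]]) == ["R40"]
    assert list(r.index[r["d2"]]) == ["R47"]
    assert list(r.index[r["d4"]]) == ["R49"]
    # constitutive gene-production fluxes depend on exactly one constant
    for fid, pname in (("R46", "d1"), ("R48", "d3"), ("R25", "d5")):
        row = r.loc[fid]
        assert list(row.index[row]) == [pname]
    # the miR production constant reaches the whole coupled oscillator
    c1 = set(r.index[r["C1"]])
    assert {"R38", "R39", "R28", "R1", "R15"} <= c1
    assert {"R46", "R48", "R25"}.isdisjoint(c1)


def test_static_mass_action_sensitivity_is_one(set3, rng):
    """S of a k*[X] flux w.r.t. k is +1 exactly, at any state."""
    state = rng.uniform(0.05, 5.0, 19)
    for fid, pname in (("R3", "k_sB"), ("R9", "k1"), ("R39", "C2"),
                       ("R40", "C4"), ("R19", "k_sC")):
        assert static_flux_sensitivity(state, set3, fid, pname) == pytest.approx(
            1.0, abs=1e-12)


def test_static_michaelis_menten_sensitivities(set3, rng):
    """V-sensitivity +1 exactly; K-sensitivity -K/(K+X) to O(delta^2)."""
    state = rng.uniform(0.2, 2.0, 19)
    assert static_flux_sensitivity(state, set3, "R2", "V_mB") == pytest.approx(
        1.0, abs=1e-12)
    x = state[3]  # M_B drives R2
    expected = -set3.K_mB / (set3.K_mB + x)
    assert static_flux_sensitivity(state, set3, "R2", "K_mB") == pytest.approx(
        expected, abs=1e-4)


def test_structurally_unreachable_pairs_are_zero(set3):
    # no integration needed: the dependency cone rules these out
    assert flux_sensitivity(set3, "R1", "C4") == 0.0
    assert flux_sensitivity(set3, "R46", "V_sB") == 0.0


def test_unknown_ids_rejected(set3):
    with pytest.raises(KeyError):
        flux_sensitivity(set3, "R99", "V_sB")
    with pytest.raises(KeyError):
        flux_sensitivity(set3, "R1", "k_stot")  # scale factors not perturbable


def test_cycle_average_reports_oscillation_death(set3):
    y, oscillatory = cycle_averaged_fluxes(set3)
    assert oscillatory and y.shape == (49,) and np.all(y >= 0)
    y2, oscillatory2 = cycle_averaged_fluxes(set3.replace(C1=1.0))
    assert not oscillatory2  # steady-state fluxes returned instead
    assert np.all(y2 >= 0)


def test_finite_difference_convergence(set3):
    """Halving delta barely moves the V_mB column (converged differences)."""
    y_base, _ = cycle_averaged_fluxes(set3)
    s1, _ = _column(set3, "V_mB", 0.01, y_base, "cycle_average")
    s2, _ = _column(set3, "V_mB", 0.005, y_base, "cycle_average")
    big = np.abs(s1) > 0.1
    rel = np.abs((s1[big] - s2[big]) / s1[big])
    assert np.median(rel) < 0.01
    # the most curved responses converge a little slower
    assert rel.max() < 0.03


def test_column_determinism(set3):
    y_base, _ = cycle_averaged_fluxes(set3)
    a, _ = _column(set3, "K_I", 0.01, y_base, "cycle_average")
    b, _ = _column(set3, "K_I", 0.01, y_base, "cycle_average")
    np.testing.assert_array_equal(a, b)


def test_matrix_shape_and_mask(smat):
    assert smat.values.shape == (49, 76)
    assert list(smat.values.index) == list(FLUX_IDS)
    assert list(smat.values.columns) == list(SENSITIVITY_PARAMS)
    r = parameter_flux_reachability()
    # masked entries are exactly zero
    assert np.all(smat.values.to_numpy()[~r.to_numpy()] == 0.0)
    # direct self-dependencies are alive
    assert smat["R38", "C3"] != 0.0
    assert smat["R46", "d1"] == pytest.approx(1.0, abs=1e-6)


def test_unmasked_structural_zeros_are_numerically_tiny(set3):
    """The mask only formalises what the finite difference already finds."""
    y_base, _ = cycle_averaged_fluxes(set3)
    s, _ = _column(set3, "C4", 0.01, y_base, "cycle_average")  # raw, no mask
    r = parameter_flux_reachability()["C4"].to_numpy()
    assert np.max(np.abs(s[~r])) < 1e-5


def test_significance_counts_summaries(smat):
    c = significance_counts(smat, threshold=1.0)
    pp = c["per_parameter"]
    assert pp.shape[0] == 76
    assert (pp["n_fluxes_significant"] >= 0).all()
    assert c["ranking"][0] == pp.index[0]
    # an infinite threshold leaves nothing significant
    c_inf = significance_counts(smat, threshold=np.inf)
    assert (c_inf["per_parameter"]["n_fluxes_significant"] == 0).all()
    with pytest.raises(ValueError):
        significance_counts(smat, threshold=0.0)


def test_matrix_requires_oscillatory_base(set3):
    with pytest.raises(ValueError):
        sensitivity_matrix(set3.replace(C1=1.0))
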