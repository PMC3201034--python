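import numpy as np
import pytest

from mirclock.model import (
    FLUXES,
    FLUX_IDS,
    N_FLUXES,
    N_SPECIES,
    SPECIES,
    STOICHIOMETRY,
    flux_table,
    fluxes,
    rhs,
    rhs_from_fluxes,
    species_index,
)


def test_registry_shapes():
    assert N_SPECIES == 19 and len(SPECIES) == 19
    assert N_FLUXES == 49
    # every flux referenced by the stoichiometry exists and vice versa
    used = {fid for inc in STOICHIOMETRY.values() for fid in inc}
    assert used == set(FLUX_IDS)


def test_zero_state_derivatives(set1):
    """At the all-zero state only constitutive terms survive."""
    d = rhs(0.0, np.zeros(19), set1)
    # Bmal1 gene: production d1 minus unrepressed transcription V_sB
    assert d[species_index("G_B")] == pytest.approx(3.6 - 0.28)
    # every term of the complex/silencing equations carries a concentration
    assert d[species_index("I_N")] == 0.0
    assert d[species_index("R_ISC")] == 0.0
    # miR-206: constitutive production only
    assert d[species_index("miR")] == pytest.approx(set1.C1)


def test_coupling_terms_vanish_without_substrates(set3, rng):
    """With M_P = miR = 0 the C3 mass-action coupling contributes nothing."""
    y = rng.uniform(0.0, 2.0, 19)
    y[species_index("M_P")] = 0.0
    y[species_index("miR")] = 0.0
    hot = rhs(0.0, y, set3)
    cold = rhs(0.0, y, set3.replace(C3=0.0))
    np.testing.assert_array_equal(hot, cold)


def test_flux_bookkeeping_reproduces_rhs(set3, rng):
    """Signed sums of registry fluxes equal the hand-written derivatives."""
    for _ in range(1000):
        y = rng.uniform(0.0, 5.0, 19)
        direct = rhs(0.0, y, set3)
        via_fluxes = rhs_from_fluxes(y, set3)
        scale = np.maximum(np.abs(direct), 1.0)
        assert np.max(np.abs(direct - via_fluxes) / scale) <= 1e-10


def test_fluxes_nonnegative_and_zero_state_maxima(set3, rng):
    v0 = fluxes(np.zeros(19), set3)
    by_id = dict(zip(FLUX_IDS, v0))
    # constitutive fluxes at their maxima at the zero state
    assert by_id["R46"] == set3.d1 and by_id["R48"] == set3.d3
    assert by_id["R25"] == set3.d5
    assert by_id["R1"] == pytest.approx(set3.V_sB)   # unrepressed Hill
    assert by_id["R27"] == pytest.approx(set3.V_s)
    assert by_id["R37"] == pytest.approx(set3.C1)    # Hill part zero at MY_C=0
    # everything carrying a concentration factor is zero
    concentration_fluxes = [f.id for f in FLUXES if f.species]
    assert all(dict(zip(FLUX_IDS, v0))[fid] == 0.0 for fid in concentration_fluxes
               if fid not in ("R1", "R27", "R37"))
    for _ in range(50):
        assert np.all(fluxes(rng.uniform(0, 10, 19), set3) >= 0.0)


def test_gene_variables_feed_nothing(set3, rng):
    """Randomising G_B, G_C, G_M leaves all other derivatives unchanged."""
    y = rng.uniform(0.1, 3.0, 19)
    y2 = y.copy()
    for g in ("G_B", "G_C", "G_M"):
        y2[species_index(g)] = rng.uniform(0, 50)
    gene_idx = [species_index(g) for g in ("G_B", "G_C", "G_M")]
    other = [i for i in range(19) if i not in gene_idx]
    np.testing.assert_array_equal(rhs(0.0, y, set3)[other],
                                  rhs(0.0, y2, set3)[other])


def test_C3_zero_decouples_mir_from_clock_mrna(set1, rng):
    """With C3 = 0, Clock mRNA dynamics ignore miR-206 and R_ISC."""
    y = rng.uniform(0.1, 3.0, 19)
    y2 = y.copy()
    y2[species_index("miR")] = 7.7
    y2[species_index("R_ISC")] = 3.3
    i = species_index("M_P")
    assert rhs(0.0, y, set1)[i] == rhs(0.0, y2, set1)[i]


def test_michaelis_constant_monotonicity(set3, rng):
    """Raising a Michaelis/inhibition constant K drives its flux term down."""
    y = rng.uniform(0.5, 2.0, 19)
    i = FLUX_IDS.index("R2")  # V_mB * M_B / (K_mB + M_B)
    vals = [fluxes(y, set3.replace(K_mB=k))[i] for k in (0.4, 4.0, 40.0, 4000.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-3 * vals[0]


def test_negative_state_handling(set3):
    y = np.zeros(19)
    y[0] = -0.5
    # clamped by default: equals evaluation at 0
    np.testing.assert_array_equal(rhs(0.0, y, set3), rhs(0.0, np.zeros(19), set3))
    with pytest.raises(ValueError):
        rhs(0.0, y, set3, clamp_negative=False)


def test_flux_table_export():
    df = flux_table()
    assert list(df["flux"]) == list(FLUX_IDS)
    assert df.shape[0] == 49
    assert set(df.columns) == {"flux", "name", "equations", "species", "parameters"}
    # each rate-equation term maps to exactly one flux: ids are unique
    assert df["flux"].is_unique
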