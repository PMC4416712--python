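"""Mutual dynamics, incompatibility, cooperativity and their invariants."""

import numpy as np
import numpy.ma as ma
import pytest

import layercascade as lc
from layercascade.errors import UndefinedAverageError, WeightError
from layercascade.metrics import (
    cooperativity_series,
    incompatibility_series,
    is_unstable,
    time_average,
)

from conftest import FAST, identity_tol, max_abs


@pytest.fixture(scope="module")
def bd_graph():
    net, fs = lc.birth_death_model()
    g = lc.populate_graph(lc.build_graph(fs), 1.0, FAST)
    return net, fs, g


@pytest.fixture(scope="module")
def random_graph():
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=6, n_reactions=9, n_functionalities=3,
                         overlap_fraction=0.25, seed=11)
    )
    g = lc.populate_graph(lc.build_graph(fs), 3.0, FAST)
    return net, fs, g


def test_birth_death_closed_forms(bd_graph):
    """M(F1;F2)(t) = t - 1 + e^-t; I(1) = e^-1; C == -1 (pure attenuation)."""
    net, fs, g = bd_graph
    M = lc.mutual_dynamics(g, "F1", "F2")
    t = M.time_grid
    assert max_abs(M.states[:, 0] - (t - 1 + np.exp(-t))) < 1e-7
    prof = lc.interaction_profile(g, "F1", "F2")
    I_end, C_end = prof.end_values()
    assert I_end == pytest.approx(np.exp(-1), abs=1e-6)
    assert C_end == pytest.approx(-1.0, abs=1e-9)
    # everywhere defined, C is exactly -1 here: M is parallel to L1+L2
    assert np.all(np.abs(prof.C.compressed() + 1.0) < 1e-6)


def test_mutual_dynamics_routes_and_symmetry(random_graph):
    net, fs, g = random_graph
    M1 = lc.mutual_dynamics(g, "F1", "F2", ["F3"])
    M2 = lc.mutual_dynamics(g, "F2", "F1", ["F3"])
    assert np.array_equal(M1.states, M2.states)  # exact pair symmetry
    Mc = lc.mutual_dynamics_via_conditional(g, "F1", "F2", ["F3"])
    scale = max(max_abs(M1.states), 1.0)
    assert max_abs(M1.states - Mc.states) < identity_tol(FAST, scale)


def test_self_mutual_dynamics_equals_conditional(random_graph):
    net, fs, g = random_graph
    M = lc.mutual_dynamics(g, "F1", "F1", ["F2"])
    L = g.conditional({0}, {1})
    assert max_abs(M.states - L.states) < 1e-12


def test_bounds_hold_everywhere_defined(random_graph):
    net, fs, g = random_graph
    for ctx in ((), ("F3",)):
        prof = lc.interaction_profile(g, "F1", "F2", ctx)
        assert np.all(prof.I.compressed() >= 0.0)
        C = prof.C.compressed()
        assert np.all((C >= -1.0) & (C <= 1.0))
        # masked points (t=0 among them) are excluded, not NaN
        assert prof.I.mask[0] and prof.C.mask[0]
        assert not np.any(np.isnan(prof.I.compressed()))


def test_disconnected_pair_has_zero_interaction():
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=6, n_reactions=8, n_functionalities=2,
                         seed=9, disconnect_blocks=True)
    )
    assert lc.structurally_disconnected_pairs(fs) == [("F1", "F2")]
    g = lc.populate_graph(lc.build_graph(fs), 3.0, FAST)
    M = lc.mutual_dynamics(g, "F1", "F2")
    assert max_abs(M.states) < identity_tol(FAST, 1.0)
    table = lc.interaction_matrix(g)
    assert set(table["category"]) == {"no_interaction"}


def test_complete_cancellation_gives_unit_incompatibility(bd_graph):
    """If the joint dynamics vanish while the isolated parts do not, the
    mutual dynamics equal the isolated sum and I = 1 (exact cancellation,
    as when a controller exactly stabilises an unstable pathway)."""
    net, fs, g = bd_graph
    LA = g.conditional({0}, frozenset())
    LB = LA.scale(0.5)
    M = LA + LB  # joint trajectory identically zero => M = L_A + L_B
    I = incompatibility_series(M, LA, LB)
    assert np.allclose(I.compressed(), 1.0)
    C = cooperativity_series(M, LA, LB)
    assert np.allclose(C.compressed(), -1.0)  # pure attenuation


def test_weighted_norm_and_weight_validation(random_graph):
    net, fs, g = random_graph
    prof_w = lc.interaction_profile(
        g, "F1", "F2", weights={s: 0.0 for s in net.species[1:]}
    )
    # zero-weighting all but one species reduces I to a scalar-output ratio;
    # with a scalar output, orthogonal dynamics are impossible: |C| = 1
    C = prof_w.C.compressed()
    if C.size:
        assert np.all(np.isclose(np.abs(C), 1.0, atol=1e-9))
    with pytest.raises(WeightError):
        lc.interaction_profile(g, "F1", "F2", weights={net.species[0]: -1.0})


def test_time_average_basics():
    t = np.linspace(0, 1, 1001)
    assert time_average(np.full(t.size, 3.3), t) == pytest.approx(3.3)
    assert time_average(t.copy(), t) == pytest.approx(0.5)
    decay = np.exp(-t)
    expect = 1 - np.exp(-1.0)
    assert time_average(decay, t) == pytest.approx(expect, rel=1e-5)
    fully_masked = ma.MaskedArray(t, mask=np.ones(t.size, bool))
    with pytest.raises(UndefinedAverageError):
        time_average(fully_masked, t)


def test_attenuation_identity(bd_graph):
    """Where C == -1, L(A,B) = (1 - I)(L_A + L_B) pointwise."""
    net, fs, g = bd_graph
    prof = lc.interaction_profile(g, "F1", "F2")
    LA = g.conditional({0}, frozenset())
    LB = g.conditional({1}, frozenset())
    joint = g.conditional({0, 1}, frozenset())
    keep = ~ma.getmaskarray(prof.I)
    lhs = joint.states[keep, 0]
    rhs = (1 - prof.I.data[keep]) * (LA.states[keep, 0] + LB.states[keep, 0])
    assert max_abs(lhs - rhs) < 1e-6


def test_interaction_matrix_enumeration(random_graph):
    net, fs, g = random_graph
    table = lc.interaction_matrix(g)
    # C(3,2) pairs x 2^(3-2) contexts = 6 rows
    assert len(table) == 6
    assert {"I_end", "C_end", "I_avg", "C_avg", "category"} <= set(table.columns)
    assert table["I_end"].notna().all()
    finite = table[["I_end", "C_end"]].to_numpy(dtype=float)
    assert np.all(np.isfinite(finite))


def test_stability_classification():
    rxns = [lc.Reaction("R1", {"X": 1.0}, lc.mass_action(1.0)),
            lc.Reaction("R2", {"X": -1.0}, lc.mass_action(1.0, {"X": 1}))]
    net = lc.ReactionNetwork(["X"], [0.0], rxns)
    fs = lc.FunctionalitySet(net, [lc.Functionality("F1", {"R1"}),
                                   lc.Functionality("F2", {"R2"})])
    g = lc.populate_graph(lc.build_graph(fs), 30.0, FAST)
    # isolated F1 grows linearly forever -> unstable; full model settles
    assert is_unstable(g.conditional({0}, frozenset()))
    table = lc.interaction_matrix(g)
    row = table.iloc[0]
    assert row["sum_unstable"] and not row["total_unstable"]
    assert row["category"] == "interaction_stabilises"
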