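"""Layer integration engine: closed forms, identities, algebra, divergence."""

import numpy as np
import pytest
from scipy.linalg import expm

import layercascade as lc
from layercascade.errors import GridMismatchError, PartitionError, StructureError

from conftest import FAST, identity_tol, max_abs


def test_isolated_layer_closed_forms(birth_death):
    net, fs = birth_death
    # birth alone: x1(t) = t
    l1 = lc.simulate_isolated_layer(fs, "F1", 1.0, FAST)
    assert l1.states[-1, 0] == pytest.approx(1.0, abs=1e-7)
    assert max_abs(l1.states[:, 0] - l1.time_grid) < 1e-7
    # decay of nothing: x2(t) = 0
    l2 = lc.simulate_isolated_layer(fs, "F2", 1.0, FAST)
    assert max_abs(l2.states) < 1e-9
    # every layer starts at zero
    assert np.all(l1.states[0] == 0)


def test_zero_rate_network_stays_at_zero():
    rxns = [lc.Reaction("R1", {"X": 1.0}, lc.mass_action(0.0))]
    net = lc.ReactionNetwork(["X"], [1.0], rxns)
    fs = lc.FunctionalitySet(net, [lc.Functionality("F1", {"R1"})])
    tr = lc.simulate_isolated_layer(fs, "F1", 2.0, FAST)
    assert max_abs(tr.states) == 0.0


def test_conditional_layer_birth_death_closed_form(birth_death):
    net, fs = birth_death
    # L(F2|F1)(t) = (1 - e^-t) - t
    tr = lc.simulate_conditional_layer(fs, "F2", "F1", 1.0, FAST)
    expect = (1 - np.exp(-tr.time_grid)) - tr.time_grid
    assert max_abs(tr.states[:, 0] - expect) < 1e-7
    assert tr.states[-1, 0] == pytest.approx(1 - np.exp(-1) - 1, abs=1e-7)


def test_conditioning_on_self_gives_zero(birth_death):
    net, fs = birth_death
    tr = lc.simulate_conditional_layer(fs, "F1", "F1", 1.0, FAST)
    assert max_abs(tr.states) < 1e-9


def test_difference_construction_agrees_with_direct(small_random):
    net, fs = small_random
    direct = lc.simulate_conditional_layer(fs, "F3", ["F1", "F2"], 3.0, FAST)
    diff = lc.conditional_via_difference(fs, "F3", ["F1", "F2"], 3.0, FAST)
    scale = max(max_abs(direct.states), 1.0)
    assert max_abs(direct.states - diff.states) < identity_tol(FAST, scale)
    assert diff.provenance == "derived_difference"
    zero = lc.conditional_via_difference(fs, "F1", "F1", 3.0, FAST)
    assert max_abs(zero.states) < identity_tol(FAST, 1.0)


def test_interpolated_upstream_matches_joint(small_random):
    net, fs = small_random
    up = lc.simulate_isolated_layer(fs, ["F1"], 3.0, FAST)
    joint = lc.simulate_conditional_layer(fs, "F2", "F1", 3.0, FAST)
    interp_opts = lc.SolverOptions(n_grid=FAST.n_grid, interpolate_upstream=True)
    replay = lc.simulate_conditional_layer(
        fs, "F2", "F1", 3.0, interp_opts, upstream=up
    )
    scale = max(max_abs(joint.states), 1.0)
    assert max_abs(joint.states - replay.states) < identity_tol(FAST, scale)


def test_strictly_downstream_chain():
    """A->B->C with the A->B rate depending only on A: layer 2 is strictly
    downstream, the altered rates vanish and the F1 layer is unchanged."""
    rxns = [
        lc.Reaction("R1", {"A": -1.0, "B": 1.0}, lc.mass_action(1.0, {"A": 1})),
        lc.Reaction("R2", {"B": -1.0, "C": 1.0}, lc.mass_action(0.5, {"B": 1})),
    ]
    net = lc.ReactionNetwork(["A", "B", "C"], [1.0, 0.0, 0.0], rxns)
    fs = lc.FunctionalitySet(
        net, [lc.Functionality("F1", {"R1"}), lc.Functionality("F2", {"R2"})]
    )
    alone = lc.simulate_isolated_layer(fs, "F1", 3.0, FAST)
    joint = lc.simulate_isolated_layer(fs, ["F1", "F2"], 3.0, FAST)
    cond = lc.simulate_conditional_layer(fs, "F2", "F1", 3.0, FAST)
    # F1's own state unchanged by adding F2: A-component identical
    assert max_abs(joint.states + 0 - (alone.states + cond.states)) < identity_tol(FAST, 1.0)
    assert max_abs(cond.states[:, 0]) < 1e-9  # A untouched by layer 2
    # altered rates vanish along the trajectory
    va = lc.altered_rates(net, net.x0 + alone.states[-1], cond.states[-1], 0.0)
    assert abs(va[0]) < 1e-9


def test_altered_rates_arithmetic():
    rxns = [
        lc.Reaction("R1", {"X": -1.0}, lc.mass_action(3.0, {"X": 1})),
        lc.Reaction("R2", {"X": -1.0}, lc.michaelis_menten(2.0, 1.0, "X")),
    ]
    net = lc.ReactionNetwork(["X"], [1.0], rxns)
    zero = lc.altered_rates(net, [1.0], [0.0])
    assert np.allclose(zero, 0.0)
    va = lc.altered_rates(net, [1.0], [1.0])
    assert va[0] == pytest.approx(3.0)  # linear: k * increment exactly
    assert va[1] == pytest.approx(2 * 2 / 3 - 1.0)  # 1/3


def test_noncascaded_partition_reconstruction(birth_death):
    net, fs = birth_death
    layers = lc.simulate_noncascaded(fs, None, 1.0, FAST)
    total = layers[0].states + layers[1].states
    expect = 1 - np.exp(-layers[0].time_grid)
    assert max_abs(total[:, 0] - expect) < 1e-7


def test_noncascaded_rejects_overlap(small_random):
    net, fs = small_random  # generated with overlap
    with pytest.raises(PartitionError):
        lc.simulate_noncascaded(fs, None, 1.0, FAST)


def test_noncascaded_sum_matches_direct_simulation():
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=4, n_reactions=7, n_functionalities=3, seed=2)
    )
    layers = lc.simulate_noncascaded(fs, None, 3.0, FAST)
    rec = lc.reconstruct_absolute(layers, net.x0)
    full = lc.simulate_full(net, 3.0, FAST)
    scale = max(max_abs(full.states), 1.0)
    assert max_abs(rec - full.states) < identity_tol(FAST, scale)


def test_single_group_noncascaded_equals_full():
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=4, n_reactions=6, n_functionalities=1, seed=3)
    )
    (layer,) = lc.simulate_noncascaded(fs, None, 3.0, FAST)
    full = lc.simulate_full(net, 3.0, FAST)
    assert max_abs(net.x0 + layer.states - full.states) < identity_tol(FAST, max_abs(full.states))


def test_linear_network_matches_matrix_exponential():
    """First-order mass-action layers obey their linear closed form."""
    rxns = [
        lc.Reaction("R1", {"A": -1.0, "B": 1.0}, lc.mass_action(0.7, {"A": 1})),
        lc.Reaction("R2", {"B": -1.0}, lc.mass_action(0.4, {"B": 1})),
    ]
    net = lc.ReactionNetwork(["A", "B"], [2.0, 1.0], rxns)
    fs = lc.FunctionalitySet(
        net, [lc.Functionality("F1", {"R1"}), lc.Functionality("F2", {"R2"})]
    )
    # isolated F1 layer: x' = S1 K (x0 + x), linear in x
    A = np.array([[-0.7, 0.0], [0.7, 0.0]])
    tr = lc.simulate_isolated_layer(fs, "F1", 2.0, FAST)
    for t in (0.5, 1.0, 2.0):
        closed = (expm(A * t) - np.eye(2)) @ net.x0
        assert max_abs(tr.at(t) - closed) < 1e-7


def test_trajectory_algebra_and_grid_errors(birth_death):
    net, fs = birth_death
    a = lc.simulate_isolated_layer(fs, "F1", 1.0, FAST)
    b = lc.simulate_isolated_layer(fs, "F2", 1.0, FAST)
    assert max_abs((a - a).states) == 0.0
    assert np.array_equal(((a + b) - b).states, a.states)
    assert np.array_equal(lc.trajectory_algebra(a, None, "negate").states, -a.states)
    assert np.array_equal(lc.trajectory_algebra(a, None, "scale", 2.0).states, 2 * a.states)
    other = lc.simulate_isolated_layer(fs, "F1", 1.0, lc.SolverOptions(n_grid=101))
    with pytest.raises(GridMismatchError):
        a + other


def test_divergence_flagging():
    """Autocatalytic blow-up is truncated and flagged, not an error."""
    rxns = [lc.Reaction("R1", {"X": 1.0}, lc.RateLaw(expr="X*X"))]
    net = lc.ReactionNetwork(["X"], [1.0], rxns)
    fs = lc.FunctionalitySet(net, [lc.Functionality("F1", {"R1"})])
    opts = lc.SolverOptions(n_grid=201, divergence_bound=1e6)
    tr = lc.simulate_isolated_layer(fs, "F1", 2.0, opts)
    assert tr.diverged and tr.t_diverged is not None
    assert tr.t_diverged < 1.1  # pole of 1/(1-t) is at t=1
    assert tr.valid_mask.sum() < tr.time_grid.size
    assert not np.any(np.isnan(tr.states[tr.valid_mask]))


def test_control_layer_reconstruction_toy():
    """Cofactor consumed by two functionalities, replenished by a control
    reaction: mixed cascade + control reproduces the direct simulation."""
    rxns = [
        lc.Reaction("R1", {"A": 1.0}, lc.mass_action(1.0)),
        lc.Reaction("R2", {"A": -1.0, "B": 1.0, "E": -1.0}, lc.mass_action(0.5, {"A": 1, "E": 1})),
        lc.Reaction("R3", {"B": -1.0, "E": -1.0}, lc.mass_action(0.3, {"B": 1, "E": 1})),
        lc.Reaction("R4", {"E": 1.0}, lc.mass_action(0.8)),
    ]
    net = lc.ReactionNetwork(["A", "B", "E"], [0.5, 0.2, 1.0], rxns)
    fs = lc.FunctionalitySet(
        net,
        [lc.Functionality("F1", {"R1", "R2"}), lc.Functionality("F2", {"R3"})],
        reserved={"R4"},
    )
    ctrl = lc.ControlLayer(species=frozenset({"E"}), reactions=frozenset({"R4"}))
    casc, z = lc.simulate_with_control_layer(fs, ctrl, None, 5.0, FAST)
    rec = lc.reconstruct_absolute(list(casc) + [z], net.x0)
    full = lc.simulate_full(net, 5.0, FAST)
    assert max_abs(rec - full.states) < identity_tol(FAST, max_abs(full.states))
    # cascade layers never move the control species
    for tr in casc:
        assert max_abs(tr.component("E")) == 0.0
    # control/cascade overlap is rejected
    bad = lc.ControlLayer(species=frozenset({"E"}), reactions=frozenset({"R3"}))
    with pytest.raises(StructureError):
        lc.simulate_with_control_layer(fs, bad, None, 1.0, FAST)


def test_empty_control_layer_equals_pure_cascade():
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=4, n_reactions=6, n_functionalities=2, seed=4)
    )
    ctrl = lc.ControlLayer(species=frozenset(), reactions=frozenset())
    casc, z = lc.simulate_with_control_layer(fs, ctrl, None, 3.0, FAST)
    assert max_abs(z.states) == 0.0
    l1 = lc.simulate_conditional_layer(fs, "F1", [], 3.0, FAST)
    l2 = lc.simulate_conditional_layer(fs, "F2", "F1", 3.0, FAST)
    scale = max(max_abs(l1.states), max_abs(l2.states), 1.0)
    assert max_abs(casc[0].states - l1.states) < identity_tol(FAST, scale)
    assert max_abs(casc[1].states - l2.states) < identity_tol(FAST, scale)


def test_reconstruction_invariant_any_ordering(small_random):
    net, fs = small_random
    full = lc.simulate_full(net, 3.0, FAST)
    for order in (["F1", "F2", "F3"], ["F3", "F1", "F2"], ["F2", "F3", "F1"]):
        trs = [
            lc.simulate_conditional_layer(fs, name, order[:i], 3.0, FAST)
            for i, name in enumerate(order)
        ]
        rec = lc.reconstruct_absolute(trs, net.x0)
        assert max_abs(rec - full.states) < identity_tol(FAST, max_abs(full.states))
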