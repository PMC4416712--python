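"""Dependency patterns, altered-reaction pruning and species omission."""

import numpy as np
import pytest

import layercascade as lc
from layercascade.network import numerical_rank, restrict_stoichiometry
from layercascade.reduction import dependency_pattern

from conftest import FAST, corpus_specs, identity_tol, max_abs


def chain_net():
    rxns = [
        lc.Reaction("R1", {"A": -1.0, "B": 1.0}, lc.mass_action(1.0, {"A": 1})),
        lc.Reaction("R2", {"B": -1.0, "C": 1.0}, lc.mass_action(0.8, {"B": 1})),
        lc.Reaction("R3", {"C": -1.0}, lc.mass_action(0.5, {"C": 1})),
    ]
    net = lc.ReactionNetwork(["A", "B", "C"], [1.0, 0.0, 0.0], rxns)
    fs = lc.FunctionalitySet(
        net,
        [lc.Functionality("F1", {"R1"}), lc.Functionality("F2", {"R2"}),
         lc.Functionality("F3", {"R3"})],
    )
    return net, fs


def test_dependency_pattern_declared_symbolic_and_probed():
    rxns = [
        lc.Reaction("R1", {"A": -1.0, "B": -1.0, "C": 1.0},
                    lc.mass_action(1.0, {"A": 1, "B": 1})),
        lc.Reaction("R2", {"C": 1.0}, lc.mass_action(2.0)),  # zero order
        lc.Reaction("R3", {"C": -1.0},
                    lc.RateLaw(func=lambda c, t: 0.5 * c["C"])),  # probed
        lc.Reaction("R4", {"A": 1.0},
                    lc.RateLaw(func=lambda c, t: 1.0, depends_on={"B"})),  # declared
    ]
    net = lc.ReactionNetwork(["A", "B", "C"], [1.0, 1.0, 1.0], rxns)
    D = dependency_pattern(net)
    assert D[0].tolist() == [True, True, False]
    assert D[1].tolist() == [False, False, False]
    assert D[2].tolist() == [False, False, True]
    assert D[3].tolist() == [False, True, False]  # declaration wins over probing


def test_controller_rate_dependencies(controller):
    net, fs = controller
    D = dependency_pattern(net)
    dep = lambda rid: {net.species[k] for k in np.flatnonzero(D[net.reaction_index(rid)])}
    assert dep("R1") == {"a"}          # input-inhibited production
    assert dep("R2") == {"y1", "b"}    # conversion inhibited by b
    assert dep("R6") == {"a"}


def test_linear_chain_pruning_both_directions():
    net, fs = chain_net()
    # downstream layer cannot feed back: all upstream altered rates prunable
    assert lc.prunable_altered_reactions(fs, "F2") == {"R1"}
    assert lc.prunable_altered_reactions(fs, "F3", ("F1", "F2")) == {"R1", "R2"}
    # upstream layer alters everything downstream of it: nothing prunable
    assert lc.prunable_altered_reactions(fs, "F1", ("F2", "F3")) == frozenset()


def test_fully_coupled_network_prunes_nothing():
    rxns = [
        lc.Reaction("R1", {"A": 1.0}, lc.RateLaw(expr="A*B")),
        lc.Reaction("R2", {"B": 1.0}, lc.RateLaw(expr="A+B")),
    ]
    net = lc.ReactionNetwork(["A", "B"], [1.0, 1.0], rxns)
    fs = lc.FunctionalitySet(
        net, [lc.Functionality("F1", {"R1"}), lc.Functionality("F2", {"R2"})]
    )
    assert lc.prunable_altered_reactions(fs, "F2") == frozenset()


def test_omittable_species_examples():
    net, fs = chain_net()
    # single-reaction layer R3 given F1,F2: C is moved; A untouched (R1, R2
    # prunable), B untouched by retained reactions
    assert lc.omittable_species(fs, "F3", ("F1", "F2")) == {"A", "B"}
    # the all-reaction layer moves every species of the model's support
    fs_all = lc.FunctionalitySet(net, [lc.Functionality("F", set(net.reaction_ids))])
    assert lc.omittable_species(fs_all, "F", ()) == frozenset()


def test_pruned_dimension_bounded_by_layer_rank(small_random):
    net, fs = small_random
    for i, f in enumerate(fs.functionalities):
        ctx = frozenset(range(i))
        om = lc.omittable_species(fs, i, ctx)
        r_l = numerical_rank(restrict_stoichiometry(
            net, fs.reactions_of(frozenset(range(i + 1)))))
        assert net.n_species - len(om) >= 0
        # retained species count is at least the layer's state-space dimension
        new = fs.reactions_of({i}) - (fs.reactions_of(ctx) if ctx else frozenset())
        r_new = numerical_rank(restrict_stoichiometry(net, new))
        assert net.n_species - len(om) >= r_new


def test_reachability_matches_indicator_exponential_small():
    """Boolean closure and the literal matrix-exponential route agree on
    every layer of a batch of small random instances (N_X, N_R <= 6)."""
    for seed in range(12):
        net, fs = lc.generate_network(
            lc.SyntheticSpec(n_species=4 + seed % 3, n_reactions=5 + seed % 2,
                             n_functionalities=2 + seed % 2, seed=seed)
        )
        for i in range(fs.n_layers):
            for ctx in ([], [j for j in range(fs.n_layers) if j != i]):
                a = lc.prunable_altered_reactions(fs, i, frozenset(ctx))
                b = lc.prunable_via_exponential(fs, i, frozenset(ctx))
                assert a == b, (seed, i, ctx)


def test_monotonicity_adding_dependency_never_enlarges_prunable():
    net, fs = chain_net()
    D = dependency_pattern(net)
    base = lc.prunable_altered_reactions(fs, "F3", ("F1", "F2"), pattern=D)
    D2 = D.copy()
    D2[0, 2] = True  # make R1's rate depend on C as well
    tighter = lc.prunable_altered_reactions(fs, "F3", ("F1", "F2"), pattern=D2)
    assert tighter <= base


@pytest.mark.parametrize("spec", corpus_specs(8), ids=lambda s: f"seed{s.seed}")
def test_pruned_layer_reproduces_unpruned(spec):
    """Soundness: simulating with certified omissions changes nothing."""
    net, fs = lc.generate_network(spec)
    n = fs.n_layers
    i = n - 1
    ctx = frozenset(range(i))
    pr = lc.prunable_altered_reactions(fs, i, ctx)
    om = lc.omittable_species(fs, i, ctx)
    plain = lc.simulate_conditional_layer(fs, {i}, ctx, 3.0, FAST)
    pruned = lc.simulate_conditional_layer(
        fs, {i}, ctx, 3.0, FAST, omit_altered=pr, omit_species=om
    )
    scale = max(max_abs(plain.states), 1.0)
    assert max_abs(plain.states - pruned.states) < identity_tol(FAST, scale)
    for s in om:
        assert max_abs(pruned.component(s)) == 0.0


def test_pruning_report_serialises(small_random, tmp_path):
    net, fs = small_random
    rep = lc.build_pruning_report(fs)
    text = rep.to_json(tmp_path / "report.json")
    assert (tmp_path / "report.json").exists()
    assert all(name in text for name in fs.names)
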