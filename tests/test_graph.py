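"""Layering graph: combinatorics, minimal simulation, Bayes rule, knockouts."""

import math
from itertools import permutations

import numpy as np
import pytest

import layercascade as lc
from layercascade.errors import GraphPopulationError
from layercascade.graph import ROOT

from conftest import FAST, identity_tol, max_abs


@pytest.fixture(scope="module")
def populated():
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=6, n_reactions=9, n_functionalities=3,
                         overlap_fraction=0.25, seed=11)
    )
    g = lc.populate_graph(lc.build_graph(fs), 3.0, FAST)
    return net, fs, g


@pytest.mark.parametrize("n_l", [1, 2, 3, 4, 5, 6, 7, 8])
def test_level_counts_match_formula(n_l):
    """Level l holds (N_L - l + 1) * C(N_L, l - 1) nodes; totals follow."""
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=4, n_reactions=max(8, n_l), n_functionalities=n_l, seed=1)
    )
    g = lc.build_graph(fs)
    for level in range(1, n_l + 1):
        expect = (n_l - level + 1) * math.comb(n_l, level - 1)
        assert len(g.level_nodes(level)) == expect
    assert g.n_nodes == n_l * 2 ** (n_l - 1)
    assert g.total_layer_dynamics == n_l * math.factorial(n_l)
    # every root-to-leaf path is one ordering
    leaves = [k for k in g.dag if k != ROOT and g.dag.out_degree(k) == 0]
    assert len(leaves) == n_l


def test_three_functionalities_structure():
    net, fs = lc.generate_network(
        lc.SyntheticSpec(n_species=4, n_reactions=8, n_functionalities=3, seed=1)
    )
    g = lc.build_graph(fs)
    assert [len(g.level_nodes(l)) for l in (1, 2, 3)] == [3, 6, 3]
    assert g.n_nodes == 12
    lc.populate_graph(g, 1.0, FAST)
    assert g.n_simulated == 2**3 - 1 == 7


def test_populate_simulates_exactly_minimal_count(populated):
    net, fs, g = populated
    assert g.n_simulated == 2**3 - 1
    assert g.populated
    # idempotent: repopulating neither resimulates nor changes anything
    before = {k: tr.provenance for k, tr in g.nodes.items()}
    lc.populate_graph(g, 3.0, FAST)
    assert {k: tr.provenance for k, tr in g.nodes.items()} == before


def test_derived_nodes_match_direct_simulation(populated):
    net, fs, g = populated
    for (i, ctx), tr in g.nodes.items():
        if tr.provenance != "derived_bayes":
            continue
        direct = lc.simulate_conditional_layer(fs, {i}, ctx, 3.0, FAST)
        scale = max(max_abs(direct.states), 1.0)
        assert max_abs(tr.states - direct.states) < identity_tol(FAST, scale)


def test_path_sum_invariance_all_orderings(populated):
    net, fs, g = populated
    full = lc.simulate_full(net, 3.0, FAST)
    scale = max(max_abs(full.states), 1.0)
    for order in permutations(range(3)):
        rec = g.path_reconstruction(order)
        assert max_abs(rec - full.states) < identity_tol(FAST, scale)


def test_simulation_cost_ratio():
    assert lc.simulation_cost_ratio(1) == 1.0
    assert lc.simulation_cost_ratio(3) == pytest.approx(18 / 7)
    assert lc.simulation_cost_ratio(10) > 3.5e4


def test_bayes_factor_identity_and_degenerate(populated):
    net, fs, g = populated
    post, fac, pri = lc.bayes_factor(g, 0, 1, 2)
    # the decomposition holds exactly by construction ...
    assert max_abs(post.states - (fac.states + pri.states)) < 1e-12
    # ... and numerically from independently simulated components
    def sim(t, c):
        return lc.simulate_conditional_layer(fs, t, c, 3.0, FAST)

    lhs = sim({2}, {0}).states - sim({1}, {0}).states
    rhs = (sim({0}, {2}).states - sim({0}, {1}).states) + (
        sim({2}, set()).states - sim({1}, set()).states
    )
    scale = max(max_abs(lhs), 1.0)
    assert max_abs(lhs - rhs) < identity_tol(FAST, scale)
    # F2 = F3: all three differences vanish
    post, fac, pri = lc.bayes_factor(g, 0, 1, 1)
    assert max_abs(post.states) == max_abs(fac.states) == max_abs(pri.states) == 0.0


def test_knockout_matches_deletion_resimulation(populated):
    net, fs, g = populated
    full = lc.simulate_full(net, 3.0, FAST)
    for targets in (["F2"], ["F3"], ["F1", "F3"]):
        eff = lc.knockout_effect(g, targets)
        others = [n for n in fs.names if n not in targets]
        exclusive = fs.reactions_of(targets) - fs.reactions_of(others)
        pruned_net = lc.ReactionNetwork(
            net.species,
            net.x0,
            [r for r in net.reactions if r.id not in exclusive],
            inputs=net.inputs.values(),
        )
        ko = lc.simulate_full(pruned_net, 3.0, FAST)
        scale = max(max_abs(full.states), 1.0)
        assert max_abs((ko.states - full.states) - eff.states) < identity_tol(FAST, scale)


def test_knockout_of_inactive_functionality_is_zero():
    rxns = [
        lc.Reaction("R1", {"A": 1.0}, lc.mass_action(1.0)),
        lc.Reaction("R2", {"B": 1.0}, lc.mass_action(0.0)),  # zero rate
    ]
    net = lc.ReactionNetwork(["A", "B"], [0.0, 0.0], rxns)
    fs = lc.FunctionalitySet(
        net, [lc.Functionality("F1", {"R1"}), lc.Functionality("F2", {"R2"})]
    )
    g = lc.populate_graph(lc.build_graph(fs), 2.0, FAST)
    eff = lc.knockout_effect(g, "F2")
    assert max_abs(eff.states) < 1e-10


def test_unpopulated_node_access_raises(populated):
    net, fs, g = populated
    fresh = lc.build_graph(fs)
    with pytest.raises(GraphPopulationError):
        fresh.node(0, frozenset({1}))


def test_dot_export_marks_simulated_nodes(populated):
    net, fs, g = populated
    dot = lc.graph_to_dot(g)
    assert dot.startswith("digraph")
    assert dot.count("peripheries=2") == 7
    assert "L(F0)" in dot


def test_export_roundtrip_files(tmp_path, populated):
    net, fs, g = populated
    lc.export_graph(g, tmp_path / "gdir")
    manifest = (tmp_path / "gdir" / "manifest.json").read_text()
    assert '"n_simulated": 7' in manifest
    assert (tmp_path / "gdir" / "graph.dot").exists()
    csvs = list((tmp_path / "gdir").glob("*.csv"))
    assert len(csvs) == g.n_nodes
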