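"""Populate the layering graph of a random 4-functionality network.

All N_L! orderings of the functionalities are represented in one DAG; the
Bayes-rule identity lets 2^N_L - 1 = 15 numerical integrations fill all
N_L * N_L! = 96 per-ordering layer dynamics.  The path sum along any ordering
reconstructs the full trajectory.
"""

from itertools import permutations

import numpy as np

import layercascade as lc

spec = lc.SyntheticSpec(n_species=8, n_reactions=12, n_functionalities=4,
                        overlap_fraction=0.3, seed=7)
net, fs = lc.generate_network(spec)
opts = lc.SolverOptions(n_grid=201)

g = lc.populate_graph(lc.build_graph(fs), 3.0, opts)
print(f"functionalities: {fs.names}")
print(f"graph nodes: {g.n_nodes}, numerically integrated: {g.n_simulated} "
      f"(= 2^{fs.n_layers} - 1), per-ordering dynamics covered: "
      f"{g.total_layer_dynamics}")
print(f"naive/minimal integration cost ratio at N_L=10: "
      f"{lc.simulation_cost_ratio(10):.3g}")

full = lc.simulate_full(net, 3.0, opts)
errs = [np.nanmax(np.abs(g.path_reconstruction(o) - full.states))
        for o in permutations(range(4))]
print(f"path-sum reconstruction error over all 24 orderings: max {max(errs):.2e}")
print()
print("Reading: every root-to-leaf path of the graph sums to the same full")
print("trajectory; only the structurally simplest member of each functionality")
print("subset was integrated, the rest follow from the Bayes-rule identity.")

dot = lc.graph_to_dot(g)
print(f"\nDOT export: {len(dot.splitlines())} lines "
      "(double-bordered nodes were simulated).")
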