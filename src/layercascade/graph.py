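"""The layering graph: all functionality orderings with minimal simulation.

Every node of the graph is a (target functionality, context subset) pair
holding one conditional-layer trajectory.  Level ``l`` (``1 <= l <= N_L``)
contains ``(N_L - l + 1) * C(N_L, l - 1)`` nodes; each root-to-leaf path spells
one of the ``N_L!`` orderings, and summing the node trajectories along any
path (plus ``x0``) reconstructs the full network trajectory.

Population requires only ``2^N_L - 1`` numerical integrations -- one per
non-empty functionality subset, choosing the structurally simplest member of
the subset as the simulated target -- and derives every other node with the
layer analogue of Bayes' rule::

    L(F1 | F2, F3) = L(F2 | F1, F3) + L(F1 | F3) - L(F2 | F3)

Multiplying a leaf node's trajectory by -1 predicts the effect of knocking
the target functionality out of the otherwise intact network.
"""

from __future__ import annotations

import json
import math
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import GraphPopulationError
from .layers import (
    LayerTrajectory,
    SolverOptions,
    reconstruct_absolute,
    simulate_conditional_layer,
)
from .network import FunctionalitySet
from .reduction import dependency_pattern, omittable_species, prunable_altered_reactions

__all__ = [
    "LayeringGraph",
    "build_graph",
    "populate_graph",
    "simulation_cost_ratio",
    "bayes_factor",
    "knockout_effect",
    "graph_to_dot",
    "export_graph",
]

ROOT = "F0"
NodeKey = tuple[int, frozenset]


class LayeringGraph:
    """DAG of all (target, context) layer nodes across levels ``0..N_L``."""

    def __init__(self, fs: FunctionalitySet):
        self.fs = fs
        self.dag = nx.DiGraph()
        self.nodes: dict[NodeKey, LayerTrajectory | None] = {}
        self.schedule: dict[frozenset, int] = {}
        self._group_cache: dict[tuple[frozenset, frozenset], LayerTrajectory] = {}
        self.horizon = None
        self.opts: SolverOptions | None = None

    # -- structure ----------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return self.fs.n_layers

    def level_nodes(self, level: int) -> list[NodeKey]:
        return [k for k in self.nodes if len(k[1]) == level - 1]

    def level_count_formula(self, level: int) -> int:
        n = self.n_layers
        return (n - level + 1) * math.comb(n, level - 1)

    @property
    def n_nodes(self) -> int:
        """Non-root (target, context) nodes: ``N_L * 2^(N_L - 1)``."""
        return len(self.nodes)

    @property
    def total_layer_dynamics(self) -> int:
        """Layer dynamics across all orderings: ``N_L * N_L!``."""
        n = self.n_layers
        return n * math.factorial(n)

    @property
    def n_simulated(self) -> int:
        return sum(
            1
            for tr in self.nodes.values()
            if tr is not None and tr.provenance == "simulated"
        )

    @property
    def populated(self) -> bool:
        return all(tr is not None for tr in self.nodes.values())

    def orderings(self):
        from itertools import permutations

        return permutations(range(self.n_layers))

    # -- node access ---------------------------------------------------------
    def _key(self, target, context) -> NodeKey:
        (i,) = self.fs.group(target)
        ctx = self.fs.group(context) if context else frozenset()
        return (i, frozenset(ctx))

    def node(self, target, context=()) -> LayerTrajectory:
        key = self._key(target, context)
        if key not in self.nodes:
            raise GraphPopulationError(f"no such node {key}")
        tr = self.nodes[key]
        if tr is None:
            raise GraphPopulationError(
                f"node {key} not populated; run populate_graph first"
            )
        return tr

    def conditional(self, targets, context=()) -> LayerTrajectory:
        """``L(targets | F^0, context)`` for an arbitrary functionality group.

        Single targets come straight from the graph; multi-functionality
        groups are assembled exactly from single-target nodes along a chain::

            L(A, B | C) = L(A | C) + L(B | A, C)

        and cached.
        """
        tg = self.fs.group(targets)
        ctx = self.fs.group(context) if context else frozenset()
        if tg & ctx:
            raise GraphPopulationError("target group overlaps its context")
        if len(tg) == 1:
            return self.node(next(iter(tg)), ctx)
        key = (frozenset(tg), frozenset(ctx))
        if key in self._group_cache:
            return self._group_cache[key]
        acc = None
        done: set[int] = set()
        for i in sorted(tg):
            tr = self.node(i, ctx | done)
            acc = tr if acc is None else acc + tr
            done.add(i)
        acc = acc.relabel(
            target=self.fs.group_names(tg),
            context=self.fs.group_names(ctx),
            provenance="derived_chain",
        )
        self._group_cache[key] = acc
        return acc

    def path_reconstruction(self, ordering: Sequence[int | str] | None = None) -> np.ndarray:
        """Absolute full-network trajectory from one root-to-leaf path."""
        order = (
            list(range(self.n_layers))
            if ordering is None
            else [self.fs.index(k) for k in ordering]
        )
        trs = []
        for pos, i in enumerate(order):
            trs.append(self.node(i, frozenset(order[:pos])))
        return reconstruct_absolute(trs, self.fs.x0)


def build_graph(fs: FunctionalitySet) -> LayeringGraph:
    """Build the node/edge structure and the minimal-simulation schedule.

    For every non-empty subset of functionalities exactly one member is marked
    for numerical simulation: the one whose conditional layer is structurally
    simplest (fewest species with nonzero dynamics, then fewest active
    reactions, ties broken by functionality index).
    """
    g = LayeringGraph(fs)
    n = fs.n_layers
    idx = range(n)
    g.dag.add_node(ROOT)
    for i in idx:
        for csize in range(n):
            for ctx in combinations((j for j in idx if j != i), csize):
                key = (i, frozenset(ctx))
                g.nodes[key] = None
                g.dag.add_node(key)
    for (i, ctx) in list(g.nodes):
        if not ctx:
            g.dag.add_edge(ROOT, (i, ctx))
        for j in idx:
            if j != i and j not in ctx:
                g.dag.add_edge((i, ctx), (j, ctx | {i}))

    D = dependency_pattern(fs.network)
    n_x = fs.network.n_species
    for size in range(1, n + 1):
        for U in combinations(idx, size):
            U = frozenset(U)
            best = None
            for i in sorted(U):
                ctx = U - {i}
                n_sp = n_x - len(omittable_species(fs, i, ctx, pattern=D))
                new_rxns = fs.reactions_of({i}) - (
                    fs.reactions_of(ctx) if ctx else frozenset()
                )
                kept_alt = (
                    (fs.reactions_of(ctx) - prunable_altered_reactions(fs, i, ctx, pattern=D))
                    if ctx
                    else frozenset()
                )
                cost = (n_sp, len(new_rxns) + len(kept_alt), i)
                if best is None or cost < best[0]:
                    best = (cost, i)
            g.schedule[U] = best[1]
    return g


def populate_graph(
    g: LayeringGraph, horizon, opts: SolverOptions = SolverOptions()
) -> LayeringGraph:
    """Fill every node: ``2^N_L - 1`` integrations, the rest via Bayes' rule.

    Derivations run strictly level by level so their inputs always exist.
    Re-running is idempotent: already-populated nodes are kept.  Nodes derived
    from diverged inputs inherit the shortest valid horizon and the flag.
    """
    fs = g.fs
    n = g.n_layers
    g.horizon = horizon
    g.opts = opts
    for size in range(1, n + 1):
        for U in combinations(range(n), size):
            U = frozenset(U)
            j = g.schedule[U]
            key = (j, U - {j})
            if g.nodes[key] is None:
                g.nodes[key] = simulate_conditional_layer(
                    fs, {j}, U - {j}, horizon, opts
                )
        for U in combinations(range(n), size):
            U = frozenset(U)
            j = g.schedule[U]
            for i in sorted(U - {j}):
                key = (i, U - {i})
                if g.nodes[key] is not None:
                    continue
                sim = g.nodes[(j, U - {j})]
                a = g.nodes[(i, U - {i, j})]
                b = g.nodes[(j, U - {i, j})]
                if sim is None or a is None or b is None:
                    raise GraphPopulationError(f"inputs missing for node {key}")
                tr = (sim + a) - b
                g.nodes[key] = tr.relabel(
                    target=(fs.functionalities[i].name,),
                    context=fs.group_names(U - {i}),
                    provenance="derived_bayes",
                )
    return g


def simulation_cost_ratio(n: int) -> float:
    """Naive-over-minimal integration count: ``((n+1)! - n!) / (2^n - 1)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (math.factorial(n + 1) - math.factorial(n)) / (2**n - 1)


def bayes_factor(
    g: LayeringGraph, F1, F2, F3, context=()
) -> tuple[LayerTrajectory, LayerTrajectory, LayerTrajectory]:
    """Decompose the choice between extending ``F1`` with ``F2`` or ``F3``.

    Returns ``(posterior, factor, prior)`` trajectories satisfying
    ``posterior = factor + prior``::

        L(F3|F1) - L(F2|F1) = [L(F1|F3) - L(F1|F2)] + [L(F3) - L(F2)]

    all additionally conditioned on ``context``.
    """
    fs = g.fs
    c = fs.group(context) if context else frozenset()
    f1, f2, f3 = (fs.group(F) for F in (F1, F2, F3))
    posterior = g.conditional(f3, f1 | c) - g.conditional(f2, f1 | c)
    factor = g.conditional(f1, f3 | c) - g.conditional(f1, f2 | c)
    prior = g.conditional(f3, c) - g.conditional(f2, c)
    return posterior, factor, prior


def knockout_effect(g: LayeringGraph, targets) -> LayerTrajectory:
    """Predicted trajectory change when the target functionalities are removed.

    Equals ``-L(targets | F^0, all others)``: the negated leaf (or grouped
    leaf) node, with every other functionality kept intact.
    """
    tg = g.fs.group(targets)
    rest = frozenset(range(g.n_layers)) - tg
    eff = -g.conditional(tg, rest)
    return eff.relabel(provenance="knockout")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def _label(g: LayeringGraph, key) -> str:
    if key == ROOT:
        return "L(F0)"
    i, ctx = key
    names = [g.fs.functionalities[i].name]
    ctx_names = ["F0", *g.fs.group_names(ctx)]
    return f"L({names[0]} | {', '.join(ctx_names)})"


def graph_to_dot(g: LayeringGraph) -> str:
    """Graphviz DOT text; simulated nodes get double borders."""
    lines = ["digraph layering {", "  rankdir=TB;", '  node [shape=ellipse];']
    ids = {ROOT: "root"}
    for k in g.nodes:
        i, ctx = k
        ids[k] = f"n{i}_" + "_".join(str(j) for j in sorted(ctx))
    lines.append(f'  root [label="{_label(g, ROOT)}"];')
    for k, tr in g.nodes.items():
        simulated = tr is not None and tr.provenance == "simulated"
        if tr is None:
            U = frozenset({k[0]}) | k[1]
            simulated = g.schedule.get(U) == k[0]
        extra = ", peripheries=2" if simulated else ""
        lines.append(f'  {ids[k]} [label="{_label(g, k)}"{extra}];')
    for a, b in g.dag.edges:
        lines.append(f"  {ids[a]} -> {ids[b]};")
    lines.append("}")
    return "\n".join(lines)


def export_graph(g: LayeringGraph, directory) -> None:
    """Persist a populated graph: one CSV per node plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "functionalities": g.fs.names,
        "n_simulated": g.n_simulated,
        "schedule": {
            "+".join(g.fs.group_names(U)): g.fs.functionalities[j].name
            for U, j in g.schedule.items()
        },
        "nodes": [],
    }
    for (i, ctx), tr in g.nodes.items():
        if tr is None:
            continue
        stem = f"L_{g.fs.functionalities[i].name}_given_" + (
            "_".join(g.fs.group_names(ctx)) if ctx else "F0"
        )
        tr.to_csv(directory / f"{stem}.csv")
        manifest["nodes"].append(
            {
                "file": f"{stem}.csv",
                "target": list(tr.target),
                "context": list(tr.context),
                "provenance": tr.provenance,
                "diverged": tr.diverged,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (directory / "graph.dot").write_text(graph_to_dot(g))
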