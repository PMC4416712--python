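"""Structural model reduction for cascaded layers.

A conditional layer's ODE contains two ingredients: the layer's own (new)
reactions and the *altered reactions* of its context, whose rates change
because the layer's state shifts shared species concentrations.  An altered
reaction can be omitted from the layer whenever no species it depends on is
reachable -- through the context's species->reaction->species dependency
structure -- from a species the layer's own reactions move.  This is a
sufficient (conservative) condition only.

The reachability test is implemented as a boolean transitive closure of the
dependency pattern, which for indicator matrices is equivalent to testing the
zero pattern of the matrix exponential ``exp(A)`` (since ``exp(A) >= I`` and
every walk of length <= dim is captured by the closure); the closure is exact
and immune to overflow.  Both routes are exposed so they can be checked
against each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from .errors import ProbingError
from .network import FunctionalitySet, ReactionNetwork, restrict_stoichiometry

__all__ = [
    "dependency_pattern",
    "prunable_altered_reactions",
    "prunable_via_exponential",
    "omittable_species",
    "PruningReport",
    "build_pruning_report",
]


def dependency_pattern(
    network: ReactionNetwork,
    seed: int = 0,
    n_probes: int = 5,
    rel_step: float = 1e-6,
    threshold: float = 1e-12,
) -> np.ndarray:
    """Boolean ``N_R x N_X`` matrix: rate ``j`` structurally depends on species ``k``.

    Declared dependencies (``RateLaw.depends_on``) take precedence; symbolic
    rate laws are read off their free symbols; opaque callables are probed
    numerically at ``n_probes`` random positive base states, perturbing each
    species in turn (any rate change above ``threshold`` counts).
    """
    n_r, n_x = network.n_reactions, network.n_species
    D = np.zeros((n_r, n_x), dtype=bool)
    need_probe = []
    for j, r in enumerate(network.reactions):
        if r.rate.depends_on is not None:
            for sid in r.rate.depends_on:
                D[j, network.species_index(sid)] = True
        elif r.rate.symbolic:
            for name in r.rate.free_names():
                if name in network.species:
                    D[j, network.species_index(name)] = True
        else:
            need_probe.append(j)
    if need_probe:
        rng = np.random.default_rng(seed)
        scale = np.abs(network.x0) + 1.0
        for _ in range(n_probes):
            base = scale * rng.uniform(0.2, 2.0, size=n_x)
            try:
                v0 = network.rates(base, 0.0, check=True)
            except Exception as exc:  # noqa: BLE001 - rewrap with context
                raise ProbingError(f"rate probing failed at a random state: {exc}")
            for k in range(n_x):
                x = base.copy()
                x[k] += rel_step * abs(base[k]) + rel_step
                v1 = network.rates(x, 0.0)
                if not np.all(np.isfinite(v1)):
                    raise ProbingError("non-finite rate during dependency probing")
                changed = np.abs(v1 - v0) > threshold
                for j in need_probe:
                    if changed[j]:
                        D[j, k] = True
    return D


def _layer_structure(fs: FunctionalitySet, layer, context):
    """Context/new reaction sets and indicator matrices for one layer."""
    net = fs.network
    new = fs.group(layer)
    if context is None:
        # default context: everything before the layer in the set's order
        i = min(new)
        context = frozenset(range(i))
    ctx = fs.group(context) if context else frozenset()
    R_ctx = fs.reactions_of(ctx) if ctx else frozenset()
    R_new = fs.reactions_of(new) - R_ctx
    S_ctx = restrict_stoichiometry(net, R_ctx)
    S_new = restrict_stoichiometry(net, R_new) if R_new else np.zeros_like(net.S)
    return ctx, R_ctx, R_new, S_ctx, S_new


def _reach_vector(D: np.ndarray, S_ctx: np.ndarray, S_new: np.ndarray) -> np.ndarray:
    """Boolean per-reaction vector: rate j can feel the layer's own dynamics.

    ``A = I(S_ctx) I(D)`` propagates species-to-species influence through the
    context's reactions; the transitive closure (including the identity) of
    ``A`` applied to the species directly moved by the new reactions gives all
    species whose concentration the layer can perturb; ``D`` lifts that back
    to reaction rates.
    """
    A = ((S_ctx != 0).astype(int) @ D.astype(int)) > 0  # N_X x N_X
    affected = np.any(S_new != 0, axis=1)
    reach = affected.copy()
    for _ in range(A.shape[0]):
        new_reach = reach | ((A.astype(int) @ reach.astype(int)) > 0)
        if np.array_equal(new_reach, reach):
            break
        reach = new_reach
    return (D.astype(int) @ reach.astype(int)) > 0  # N_R bool


def prunable_altered_reactions(
    fs: FunctionalitySet,
    layer,
    context=None,
    pattern: np.ndarray | None = None,
) -> frozenset[str]:
    """Context reactions whose altered-rate term is provably zero for this layer.

    ``layer`` is a functionality (index or name) or group; ``context`` the
    conditioning group (defaults to all functionalities preceding ``layer``
    in the set's order).  Conservative: omitting the returned reactions never
    changes the layer's trajectory.
    """
    net = fs.network
    D = dependency_pattern(net) if pattern is None else pattern
    ctx, R_ctx, R_new, S_ctx, S_new = _layer_structure(fs, layer, context)
    hit = _reach_vector(D, S_ctx, S_new)
    return frozenset(
        rid for rid in R_ctx if not hit[net.reaction_index(rid)]
    )


def prunable_via_exponential(
    fs: FunctionalitySet,
    layer,
    context=None,
    pattern: np.ndarray | None = None,
    zero_tol: float = 1e-8,
) -> frozenset[str]:
    """Literal indicator-of-matrix-exponential evaluation of the omission test.

    Computes ``I(D) . exp(I(S_ctx) I(D)) . I(S_new) . 1`` and returns the
    context reactions with a zero entry.  Intended as an independent check of
    :func:`prunable_altered_reactions` on small instances; the exponential can
    overflow on large ones, which is why the closure is the default route.
    """
    net = fs.network
    D = dependency_pattern(net) if pattern is None else pattern
    ctx, R_ctx, R_new, S_ctx, S_new = _layer_structure(fs, layer, context)
    A = (S_ctx != 0).astype(float) @ D.astype(float)
    vec = D.astype(float) @ expm(A) @ (S_new != 0).astype(float) @ np.ones(net.n_reactions)
    return frozenset(
        rid for rid in R_ctx if abs(vec[net.reaction_index(rid)]) <= zero_tol
    )


def omittable_species(
    fs: FunctionalitySet,
    layer,
    context=None,
    pattern: np.ndarray | None = None,
) -> frozenset[str]:
    """Species with provably zero dynamics in the layer.

    A species can be left out of a layer's integration when no retained
    reaction of the layer (own reactions plus non-prunable altered reactions)
    changes its concentration.
    """
    net = fs.network
    D = dependency_pattern(net) if pattern is None else pattern
    ctx, R_ctx, R_new, S_ctx, S_new = _layer_structure(fs, layer, context)
    prunable = prunable_altered_reactions(fs, layer, context, pattern=D)
    retained = set(R_new) | (set(R_ctx) - prunable)
    cols = [net.reaction_index(r) for r in retained]
    if not cols:
        return frozenset(net.species)
    moved = np.any(net.S[:, cols] != 0, axis=1)
    return frozenset(s for i, s in enumerate(net.species) if not moved[i])


@dataclass
class PruningReport:
    """Per-layer omission certificates for one cascade ordering."""

    order: list[str]
    prunable: dict[str, list[str]] = field(default_factory=dict)
    omittable: dict[str, list[str]] = field(default_factory=dict)
    pattern: np.ndarray | None = None

    def to_json(self, path=None) -> str:
        doc = {
            "order": self.order,
            "prunable_altered_reactions": self.prunable,
            "omittable_species": self.omittable,
            "dependency_pattern": None
            if self.pattern is None
            else self.pattern.astype(int).tolist(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_pruning_report(fs: FunctionalitySet, order=None) -> PruningReport:
    """Omission report for every layer of a cascade ordering (default order)."""
    if order is None:
        order = list(range(fs.n_layers))
    order = [fs.index(k) for k in order]
    D = dependency_pattern(fs.network)
    rep = PruningReport(order=[fs.functionalities[i].name for i in order], pattern=D)
    for pos, i in enumerate(order):
        ctx = frozenset(order[:pos])
        name = fs.functionalities[i].name
        rep.prunable[name] = sorted(prunable_altered_reactions(fs, i, ctx, pattern=D))
        rep.omittable[name] = sorted(omittable_species(fs, i, ctx, pattern=D))
    return rep
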