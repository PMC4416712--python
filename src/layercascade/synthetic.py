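"""Reproducible random reaction networks with functionality covers.

The generator emulates the inputs the framework consumes: sparse random
stoichiometries with a mix of zero-order, first-order, bimolecular mass-action
and Michaelis-Menten kinetics, and a random cover of the reaction set by
ordered functionalities (a strict partition when ``overlap_fraction`` is 0).
All rate laws are symbolic, so generated networks export to SBML and give
exact dependency patterns.  No generated reaction is autocatalytic, so
trajectories grow at most linearly and the identity suites integrate cleanly.

With ``disconnect_blocks=True`` the species are split into disjoint pools,
one per functionality, and every reaction stays inside its pool: the
functionalities are then structurally disconnected, which downstream forces
their mutual dynamics to vanish identically (the zero-coupling tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SyntheticSpecError
from .network import (
    Functionality,
    FunctionalitySet,
    RateLaw,
    Reaction,
    ReactionNetwork,
    mass_action,
    michaelis_menten,
)

__all__ = ["SyntheticSpec", "generate_network", "structurally_disconnected_pairs"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a random network + functionality cover."""

    n_species: int = 6
    n_reactions: int = 10
    n_functionalities: int = 3
    overlap_fraction: float = 0.0
    #: proportions of (zero-order, first-order, bimolecular, Michaelis-Menten)
    kinetics_mix: tuple[float, float, float, float] = (0.2, 0.4, 0.2, 0.2)
    seed: int = 0
    k_range: tuple[float, float] = (0.2, 1.0)
    km_range: tuple[float, float] = (0.5, 2.0)
    x0_range: tuple[float, float] = (0.5, 2.0)
    disconnect_blocks: bool = False

    def validate(self):
        if self.n_functionalities > self.n_reactions:
            raise SyntheticSpecError(
                "more functionalities than reactions: cover infeasible"
            )
        if self.n_species < 2 or self.n_reactions < 1:
            raise SyntheticSpecError("need at least 2 species and 1 reaction")
        if not np.isclose(sum(self.kinetics_mix), 1.0):
            raise SyntheticSpecError("kinetics_mix must sum to 1")
        if self.disconnect_blocks and self.n_species < 2 * self.n_functionalities:
            raise SyntheticSpecError(
                "disconnected blocks need >= 2 species per functionality"
            )


def _random_reaction(rid, kind, pool, rng, spec) -> Reaction:
    k = rng.uniform(*spec.k_range)
    if kind == 0:  # zero order inflow
        target = rng.choice(pool)
        return Reaction(rid, {target: 1.0}, mass_action(k))
    if kind == 1:  # first order conversion or decay
        src = rng.choice(pool)
        if len(pool) > 1 and rng.random() < 0.7:
            dst = rng.choice([s for s in pool if s != src])
            return Reaction(rid, {src: -1.0, dst: 1.0}, mass_action(k, {src: 1}))
        return Reaction(rid, {src: -1.0}, mass_action(k, {src: 1}))
    if kind == 2:  # bimolecular A + B -> C (or -> nothing if pool tiny)
        a, b = rng.choice(pool, size=2, replace=False)
        stoich = {a: -1.0, b: -1.0}
        rest = [s for s in pool if s not in (a, b)]
        if rest:
            stoich[rng.choice(rest)] = 1.0
        return Reaction(rid, stoich, mass_action(k, {a: 1, b: 1}))
    # Michaelis-Menten conversion
    src = rng.choice(pool)
    km = rng.uniform(*spec.km_range)
    stoich = {src: -1.0}
    rest = [s for s in pool if s != src]
    if rest:
        stoich[rng.choice(rest)] = 1.0
    return Reaction(rid, stoich, michaelis_menten(k, km, src))


def generate_network(spec: SyntheticSpec) -> tuple[ReactionNetwork, FunctionalitySet]:
    """Generate a reproducible random network and functionality cover.

    Identical specs (including seed) give bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    species = [f"X{i + 1}" for i in range(spec.n_species)]
    x0 = rng.uniform(*spec.x0_range, size=spec.n_species)

    n_f = spec.n_functionalities
    if spec.disconnect_blocks:
        # disjoint species pools, one per functionality
        perm = list(rng.permutation(spec.n_species))
        bounds = np.linspace(0, spec.n_species, n_f + 1).astype(int)
        pools = [
            [species[perm[i]] for i in range(bounds[b], bounds[b + 1])]
            for b in range(n_f)
        ]
        owner = [b for j in range(spec.n_reactions) for b in [j % n_f]]
    else:
        pools = [species] * n_f
        owner = [j % n_f for j in range(spec.n_reactions)]

    kinds = rng.choice(4, size=spec.n_reactions, p=spec.kinetics_mix)
    reactions = []
    for j in range(spec.n_reactions):
        pool = pools[owner[j]]
        kind = int(kinds[j])
        if kind == 2 and len(pool) < 2:
            kind = 1
        reactions.append(_random_reaction(f"R{j + 1}", kind, pool, rng, spec))

    net = ReactionNetwork(
        species, x0, reactions, name=f"synthetic_seed{spec.seed}"
    )

    # cover: deal reactions round-robin (each functionality non-empty), then
    # optionally let reactions join a second functionality
    groups: list[set[str]] = [set() for _ in range(n_f)]
    order = rng.permutation(spec.n_reactions)
    for pos, j in enumerate(order):
        groups[owner[j] if spec.disconnect_blocks else pos % n_f].add(f"R{j + 1}")
    if spec.overlap_fraction > 0 and not spec.disconnect_blocks:
        for j in range(spec.n_reactions):
            if rng.random() < spec.overlap_fraction:
                current = next(b for b, grp in enumerate(groups) if f"R{j + 1}" in grp)
                others = [b for b in range(n_f) if b != current]
                groups[int(rng.choice(others))].add(f"R{j + 1}")
    fs = FunctionalitySet(
        net,
        [Functionality(f"F{b + 1}", frozenset(grp)) for b, grp in enumerate(groups)],
    )
    return net, fs


def structurally_disconnected_pairs(fs: FunctionalitySet) -> list[tuple[str, str]]:
    """Functionality pairs sharing no species (stoichiometric or rate-law).

    Such pairs cannot interact: their mutual dynamics vanish identically in
    any context that preserves the disconnection.
    """
    from .reduction import dependency_pattern

    net = fs.network
    D = dependency_pattern(net)
    touch = []
    for f in fs.functionalities:
        sp: set[int] = set()
        for rid in f.reactions:
            j = net.reaction_index(rid)
            sp |= set(np.flatnonzero(net.S[:, j] != 0))
            sp |= set(np.flatnonzero(D[j]))
        touch.append(sp)
    out = []
    for a in range(fs.n_layers):
        for b in range(a + 1, fs.n_layers):
            if not (touch[a] & touch[b]):
                out.append((fs.functionalities[a].name, fs.functionalities[b].name))
    return out
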