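"""Kinetic reaction-network models.

A :class:`ReactionNetwork` holds species with initial concentrations, reactions
with stoichiometry and rate laws, and optional time-varying input signals.  The
network ODE is ``x' = S v(x, t)`` where ``S`` is the stoichiometric matrix
(``N_X`` species rows by ``N_R`` reaction columns) and ``v`` the rate vector.

Rate laws are either sympy expressions over species identifiers, input-signal
names and ``t`` (preferred: they can be exported to SBML and yield exact
dependency patterns), or arbitrary Python callables ``f(conc, t) -> float``
where ``conc`` maps species and input names to current values.  The engine
never differentiates rate laws symbolically.

Functionalities are named, possibly overlapping subsets of reaction identifiers
whose union covers the reaction set.  The constant "zero layer" holding the
initial conditions is represented implicitly by :attr:`FunctionalitySet.x0`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

from .errors import (
    CoverError,
    RateEvaluationError,
    ScheduleError,
    UnknownReactionError,
    UnknownSpeciesError,
)

__all__ = [
    "InputSignal",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "Functionality",
    "FunctionalitySet",
    "mass_action",
    "michaelis_menten",
    "restrict_stoichiometry",
    "layer_dimension",
    "evaluate_rates",
    "numerical_rank",
]

#: Relative singular-value cutoff used for numerical matrix rank.
RANK_TOLERANCE = 1e-10


class InputSignal:
    """A named time-varying input referenced by rate laws.

    Either a piecewise-constant ``schedule`` of ``(t_start, t_end, value)``
    segments (``t_end=None`` means "until forever") or a general callable
    ``func(t)``.  Segments must not overlap; evaluation outside every segment
    raises :class:`~layercascade.errors.ScheduleError`.
    """

    def __init__(
        self,
        name: str,
        schedule: Sequence[tuple[float, float | None, float]] | None = None,
        func: Callable[[float], float] | None = None,
        expr: sp.Expr | None = None,
    ):
        if (schedule is None) == (func is None and expr is None):
            raise ValueError("provide exactly one of schedule or func/expr")
        self.name = name
        self.expr = expr
        if expr is not None and func is None:
            func = sp.lambdify(sp.Symbol("t"), expr, modules="numpy")
        self.func = func
        if schedule is not None:
            segs = []
            for t0, t1, val in schedule:
                t1 = math.inf if t1 is None else float(t1)
                segs.append((float(t0), t1, float(val)))
            segs.sort(key=lambda s: s[0])
            for (a0, a1, _), (b0, _, _) in zip(segs, segs[1:]):
                if b0 < a1 - 1e-12:
                    raise ValueError(f"overlapping segments in schedule of {name!r}")
            self.schedule = segs
        else:
            self.schedule = None

    def __call__(self, t: float) -> float:
        if self.schedule is None:
            return float(self.func(t))
        for t0, t1, val in self.schedule:
            # segments are half-open [t0, t1); the last one is closed at +inf
            if t0 <= t < t1 or (t == t1 == math.inf):
                return val
        # tolerate the exact right endpoint of the final finite segment
        t0, t1, val = self.schedule[-1]
        if t == t1:
            return val
        raise ScheduleError(
            f"time t={t} outside every segment of input schedule {self.name!r}"
        )

    def breakpoints(self) -> list[float]:
        """Interior discontinuity times (integrator restart points)."""
        if self.schedule is None:
            return []
        pts = {t0 for t0, _, _ in self.schedule[1:]}
        pts.update(t1 for _, t1, _ in self.schedule if math.isfinite(t1))
        return sorted(pts)


class RateLaw:
    """A reaction rate law: a sympy expression or an opaque callable.

    Parameters
    ----------
    expr:
        sympy expression over species ids, input names and ``t``.  Numeric
        parameters should already be substituted (or passed via ``params``).
    func:
        callable ``f(conc, t)`` where ``conc`` maps species/input names to
        values.  Used when no expression is given.
    depends_on:
        optional declared set of species ids the rate depends on; used by the
        model-reduction module in preference to numerical probing.
    """

    def __init__(
        self,
        expr: sp.Expr | None = None,
        func: Callable | None = None,
        params: Mapping[str, float] | None = None,
        depends_on: set[str] | None = None,
    ):
        if (expr is None) == (func is None):
            raise ValueError("provide exactly one of expr or func")
        if expr is not None and params:
            expr = sp.sympify(expr).subs({sp.Symbol(k): v for k, v in params.items()})
        self.expr = sp.sympify(expr) if expr is not None else None
        self.func = func
        self.depends_on = set(depends_on) if depends_on is not None else None

    @property
    def symbolic(self) -> bool:
        return self.expr is not None

    def free_names(self) -> set[str]:
        if self.expr is None:
            return set()
        return {str(s) for s in self.expr.free_symbols}


def mass_action(k: float, reactants: Mapping[str, int] | None = None) -> RateLaw:
    """Mass-action rate ``k * prod(x_i^n_i)``; empty reactants = zero order."""
    expr = sp.Float(k)
    for sid, order in (reactants or {}).items():
        expr = expr * sp.Symbol(sid) ** int(order)
    return RateLaw(expr=expr)


def michaelis_menten(vmax: float, km: float, substrate: str) -> RateLaw:
    """Michaelis-Menten rate ``vmax * x / (km + x)``."""
    x = sp.Symbol(substrate)
    return RateLaw(expr=sp.Float(vmax) * x / (sp.Float(km) + x))


@dataclass
class Reaction:
    """One reaction: identifier, stoichiometry column, rate law."""

    id: str
    stoich: dict[str, float]
    rate: RateLaw
    reversible: bool = False


class _Conc(dict):
    """State mapping passed to callable rate laws; raises on unknown names."""

    def __missing__(self, key):
        raise UnknownSpeciesError(f"unknown species or input {key!r} in rate law")


class ReactionNetwork:
    """A kinetic model ``x' = S v(x, t)`` with initial state ``x0``."""

    def __init__(
        self,
        species: Sequence[str],
        x0: Sequence[float],
        reactions: Sequence[Reaction],
        inputs: Iterable[InputSignal] = (),
        name: str = "network",
    ):
        self.name = name
        self.species = list(species)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species identifiers")
        self.x0 = np.asarray(x0, dtype=float)
        if self.x0.shape != (len(self.species),):
            raise ValueError("x0 must have one entry per species")
        if not np.all(np.isfinite(self.x0)):
            raise ValueError("x0 must be finite")
        self.reactions = list(reactions)
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction identifiers")
        self.inputs = {sig.name: sig for sig in inputs}
        self._sidx = {s: i for i, s in enumerate(self.species)}
        self._ridx = {r.id: j for j, r in enumerate(self.reactions)}
        for r in self.reactions:
            for sid in r.stoich:
                if sid not in self._sidx:
                    raise UnknownSpeciesError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
        self.S = np.zeros((self.n_species, self.n_reactions))
        for j, r in enumerate(self.reactions):
            for sid, coef in r.stoich.items():
                self.S[self._sidx[sid], j] = coef
        self._compiled = None

    # -- basic introspection -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self, sid: str) -> int:
        try:
            return self._sidx[sid]
        except KeyError:
            raise UnknownSpeciesError(f"unknown species {sid!r}") from None

    def reaction_index(self, rid: str) -> int:
        try:
            return self._ridx[rid]
        except KeyError:
            raise UnknownReactionError(f"unknown reaction {rid!r}") from None

    def check_reaction_ids(self, rids: Iterable[str]) -> frozenset[str]:
        rids = frozenset(rids)
        for rid in rids:
            self.reaction_index(rid)
        return rids

    def input_breakpoints(self) -> list[float]:
        pts: set[float] = set()
        for sig in self.inputs.values():
            pts.update(sig.breakpoints())
        return sorted(pts)

    # -- rate evaluation -----------------------------------------------------
    def _compile(self):
        """Build per-reaction fast evaluators (lambdified where symbolic)."""
        if self._compiled is not None:
            return self._compiled
        argnames = self.species + list(self.inputs)
        syms = [sp.Symbol(n) for n in argnames] + [sp.Symbol("t")]
        fns = []
        for r in self.reactions:
            if r.rate.symbolic:
                unknown = r.rate.free_names() - set(argnames) - {"t"}
                if unknown:
                    raise RateEvaluationError(
                        f"rate of {r.id!r} references unknown names {sorted(unknown)}"
                    )
                fns.append(("sym", sp.lambdify(syms, r.rate.expr, modules="numpy")))
            else:
                fns.append(("call", r.rate.func))
        self._compiled = (argnames, fns)
        return self._compiled

    def rates(self, x: np.ndarray, t: float = 0.0, check: bool = False) -> np.ndarray:
        """Evaluate the rate vector ``v(x, t)`` (length ``N_R``)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise ValueError(f"state must have length {self.n_species}")
        argnames, fns = self._compile()
        inputvals = [self.inputs[n](t) for n in self.inputs]
        args = list(x) + inputvals + [t]
        conc = None
        v = np.empty(self.n_reactions)
        for j, (kind, fn) in enumerate(fns):
            if kind == "sym":
                v[j] = fn(*args)
            else:
                if conc is None:
                    conc = _Conc(zip(argnames, list(x) + inputvals))
                    conc["t"] = t
                v[j] = fn(conc, t)
        if check and not np.all(np.isfinite(v)):
            bad = [self.reactions[j].id for j in np.flatnonzero(~np.isfinite(v))]
            raise RateEvaluationError(f"non-finite rate(s) for reaction(s) {bad}")
        return v

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReactionNetwork({self.name!r}, N_X={self.n_species}, "
            f"N_R={self.n_reactions})"
        )


def evaluate_rates(network: ReactionNetwork, x, t: float = 0.0) -> np.ndarray:
    """Evaluate ``v(x, t)``, raising on non-finite rates (public entry point)."""
    return network.rates(np.asarray(x, dtype=float), t, check=True)


def restrict_stoichiometry(network: ReactionNetwork, F: Iterable[str]) -> np.ndarray:
    """Stoichiometric matrix with only the columns of reactions in ``F`` kept.

    The returned matrix has the same shape as ``S``; columns of reactions not
    in ``F`` are zero.  Restriction distributes over unions by inclusion-
    exclusion, and summing over a strict partition of the reaction set
    recovers ``S`` exactly.
    """
    F = network.check_reaction_ids(F)
    SF = np.zeros_like(network.S)
    for rid in F:
        j = network.reaction_index(rid)
        SF[:, j] = network.S[:, j]
    return SF


def numerical_rank(M: np.ndarray, tol: float = RANK_TOLERANCE) -> int:
    """Rank with singular values below ``tol * s_max`` counted as zero."""
    if M.size == 0 or not np.any(M):
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    return int(np.sum(s > tol * s[0]))


def layer_dimension(
    network: ReactionNetwork, F: Iterable[str], tol: float = RANK_TOLERANCE
) -> int:
    """Dimension ``r^F = rank(S^F)`` of the layer spanned by reactions ``F``."""
    return numerical_rank(restrict_stoichiometry(network, F), tol)


@dataclass(frozen=True)
class Functionality:
    """A named, non-empty subset of reactions fulfilling one task."""

    name: str
    reactions: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "reactions", frozenset(self.reactions))
        if not self.reactions:
            raise ValueError(f"functionality {self.name!r} has no reactions")


class FunctionalitySet:
    """An ordered list of functionalities covering a network's reactions.

    Functionalities may overlap.  The implicit zero layer ``F^0`` is the
    constant trajectory at the network's initial conditions ``x0``.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        functionalities: Sequence[Functionality],
        reserved: Iterable[str] = (),
    ):
        if not functionalities:
            raise ValueError("need at least one functionality")
        names = [f.name for f in functionalities]
        if len(set(names)) != len(names):
            raise ValueError("duplicate functionality names")
        self.network = network
        self.functionalities = list(functionalities)
        self.reserved = network.check_reaction_ids(reserved)
        union: set[str] = set()
        for f in self.functionalities:
            network.check_reaction_ids(f.reactions)
            if f.reactions & self.reserved:
                raise CoverError(
                    f"functionality {f.name!r} uses reserved (control) reactions"
                )
            union |= f.reactions
        missing = set(network.reaction_ids) - union - set(self.reserved)
        if missing:
            raise CoverError(
                f"reactions not covered by any functionality: {sorted(missing)}"
            )
        self._by_name = {f.name: i for i, f in enumerate(self.functionalities)}

    @classmethod
    def from_dict(
        cls, network: ReactionNetwork, groups: Mapping[str, Iterable[str]]
    ) -> "FunctionalitySet":
        return cls(
            network, [Functionality(name, frozenset(r)) for name, r in groups.items()]
        )

    @property
    def n_layers(self) -> int:
        return len(self.functionalities)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.functionalities]

    @property
    def x0(self) -> np.ndarray:
        """The zero layer F^0: the constant initial-condition trajectory."""
        return self.network.x0

    def index(self, key: int | str) -> int:
        if isinstance(key, str):
            if key not in self._by_name:
                raise KeyError(f"unknown functionality {key!r}")
            return self._by_name[key]
        if not 0 <= key < self.n_layers:
            raise KeyError(f"functionality index {key} out of range")
        return key

    def group(self, keys: int | str | Iterable[int | str]) -> frozenset[int]:
        """Normalise a functionality group to a frozenset of indices."""
        if isinstance(keys, (int, str)):
            keys = [keys]
        return frozenset(self.index(k) for k in keys)

    def reactions_of(self, keys) -> frozenset[str]:
        """Union of reaction ids over a functionality group."""
        out: set[str] = set()
        for i in self.group(keys):
            out |= self.functionalities[i].reactions
        return frozenset(out)

    def group_names(self, group: Iterable[int]) -> tuple[str, ...]:
        return tuple(self.functionalities[i].name for i in sorted(group))

    def is_partition(self, groups: Sequence[Iterable[str]]) -> bool:
        seen: set[str] = set()
        for g in groups:
            g = set(g)
            if g & seen:
                return False
            seen |= g
        return seen == set(self.network.reaction_ids) - set(self.reserved)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FunctionalitySet({self.names}, N_L={self.n_layers})"
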