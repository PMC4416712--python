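"""Cascaded layer ODE construction and integration.

A *layer* is an ODE subsystem whose state is the incremental concentration
change attributable to one functionality group given a conditioning context.
Layer states start at zero and legitimately go negative; only the
reconstructed absolute state ``x0 + sum of layers`` is physically meaningful.

The three layer forms implemented here:

* isolated layer of a group ``F`` (context = initial conditions only)::

      x'^F = S^F v(x0 + x^F)

* conditional layer of ``F_new`` given context group ``C`` (the context state
  is integrated jointly by default, or replayed from a stored upstream
  trajectory through monotone-cubic interpolation)::

      x'^new = S^{C u new} v(x0 + x^C + x^new) - S^C v(x0 + x^C)

* non-cascaded layering of a strict partition, all layers integrated
  simultaneously, each seeing the sum of all layer states.

Divergence is data, not failure: integration aborts once the state norm
exceeds a configurable bound, the trajectory is kept up to the abort time
(later grid points are left blank) and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .errors import (
    GridMismatchError,
    PartitionError,
    SolverError,
    StructureError,
)
from .network import FunctionalitySet, ReactionNetwork, restrict_stoichiometry

__all__ = [
    "SolverOptions",
    "LayerTrajectory",
    "simulate_full",
    "simulate_isolated_layer",
    "simulate_conditional_layer",
    "conditional_via_difference",
    "simulate_noncascaded",
    "altered_rates",
    "trajectory_algebra",
    "reconstruct_absolute",
    "ControlLayer",
    "simulate_with_control_layer",
]


@dataclass(frozen=True)
class SolverOptions:
    """Integration settings shared by every layer of one analysis.

    ``n_grid`` points are placed uniformly over the horizon; all trajectory
    algebra and interaction metrics operate on this shared grid.  The solver
    restarts at input-schedule breakpoints so discontinuities are not smoothed
    over.  ``divergence_bound`` is the max-norm of the (stacked) layer state
    beyond which integration is aborted and the trajectory flagged.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    n_grid: int = 1001
    divergence_bound: float = 1e9
    interpolate_upstream: bool = False
    max_step: float = np.inf


@dataclass
class LayerTrajectory:
    """The time course of one layer's state on a shared grid.

    ``states`` has shape ``(N_T, N_X)``.  Rows after a divergence abort are
    NaN; :attr:`valid_mask` marks usable grid points.  ``target`` and
    ``context`` are tuples of functionality names; the zero layer ``F^0`` is
    implicit in every context.
    """

    target: tuple[str, ...]
    context: tuple[str, ...]
    time_grid: np.ndarray
    states: np.ndarray
    species: list[str]
    provenance: str = "simulated"
    diverged: bool = False
    t_diverged: float | None = None
    #: dense solver output (list of per-segment OdeSolution), kept only on
    #: directly simulated trajectories; algebra results drop it
    dense: list | None = None

    def interpolate(self, t: float) -> np.ndarray:
        """State at an off-grid time: dense solver output if available,
        monotone cubic on the grid otherwise."""
        if self.dense:
            t = min(max(t, self.dense[0].t_min), self.dense[-1].t_max)
            for seg in self.dense:
                if t <= seg.t_max:
                    return np.asarray(seg(t))[: len(self.species)]
            return np.asarray(self.dense[-1](self.dense[-1].t_max))[: len(self.species)]
        mask = self.valid_mask
        interp = PchipInterpolator(
            self.time_grid[mask], self.states[mask], axis=0, extrapolate=True
        )
        return interp(t)

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.time_grid.size, len(self.species)):
            raise ValueError("states must be (N_T, N_X)")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.any(np.isnan(self.states), axis=1)

    def component(self, sid: str) -> np.ndarray:
        return self.states[:, self.species.index(sid)]

    def at(self, t: float) -> np.ndarray:
        """State at grid time ``t`` (must be a grid point)."""
        i = int(np.argmin(np.abs(self.time_grid - t)))
        if not np.isclose(self.time_grid[i], t):
            raise GridMismatchError(f"t={t} is not on the time grid")
        return self.states[i]

    # -- trajectory algebra (exact pointwise arithmetic, shared grid only) --
    def _check_grid(self, other: "LayerTrajectory"):
        if not np.array_equal(self.time_grid, other.time_grid):
            raise GridMismatchError("trajectories do not share a time grid")
        if self.species != other.species:
            raise GridMismatchError("trajectories have different species")

    def _combine(self, other, states, provenance):
        return LayerTrajectory(
            target=self.target,
            context=self.context,
            time_grid=self.time_grid,
            states=states,
            species=self.species,
            provenance=provenance,
            diverged=self.diverged or other.diverged,
            t_diverged=_min_opt(self.t_diverged, other.t_diverged),
        )

    def __add__(self, other: "LayerTrajectory") -> "LayerTrajectory":
        self._check_grid(other)
        return self._combine(other, self.states + other.states, "algebra")

    def __sub__(self, other: "LayerTrajectory") -> "LayerTrajectory":
        self._check_grid(other)
        return self._combine(other, self.states - other.states, "algebra")

    def __neg__(self) -> "LayerTrajectory":
        return replace(self, states=-self.states, provenance="algebra", dense=None)

    def scale(self, c: float) -> "LayerTrajectory":
        return replace(self, states=c * self.states, provenance="algebra", dense=None)

    def relabel(self, target=None, context=None, provenance=None) -> "LayerTrajectory":
        out = replace(self)
        if target is not None:
            out.target = tuple(target)
        if context is not None:
            out.context = tuple(context)
        if provenance is not None:
            out.provenance = provenance
        return out

    # -- export -------------------------------------------------------------
    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time", self.time_grid)
        return df

    def to_csv(self, path, sidecar: dict | None = None):
        """Write a CSV (time + one column per species) and a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "target": list(self.target),
            "context": list(self.context),
            "provenance": self.provenance,
            "diverged": self.diverged,
            "t_diverged": self.t_diverged,
        }
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _min_opt(a, b):
    vals = [v for v in (a, b) if v is not None]
    return min(vals) if vals else None


def trajectory_algebra(
    a: LayerTrajectory, b: LayerTrajectory | None, op: str, scalar: float = 1.0
) -> LayerTrajectory:
    """Pointwise arithmetic on trajectories sharing a grid.

    Floating-point note: ``(a + b) - b`` recovers ``a`` exactly only when no
    rounding occurs in the sum; over the magnitudes arising here the identity
    holds to machine precision, which is what the tests assert.
    """
    if op == "add":
        return a + b
    if op == "subtract":
        return a - b
    if op == "negate":
        return -a
    if op == "scale":
        return a.scale(scalar)
    raise ValueError(f"unknown op {op!r}")


# ---------------------------------------------------------------------------
# integration driver
# ---------------------------------------------------------------------------


def _time_grid(horizon: float | tuple[float, float], n: int) -> np.ndarray:
    if isinstance(horizon, (tuple, list)):
        t0, t1 = horizon
    else:
        t0, t1 = 0.0, float(horizon)
    if not t1 > t0:
        raise ValueError("horizon must be positive")
    return np.linspace(t0, t1, n)


def _integrate(
    rhs: Callable,
    y0: np.ndarray,
    grid: np.ndarray,
    breakpoints: Sequence[float],
    opts: SolverOptions,
    want_dense: bool = False,
) -> tuple[np.ndarray, bool, float | None, list | None]:
    """Piecewise integration with divergence abort.

    Returns ``(states_on_grid, diverged, t_diverged, dense_segments)`` where
    ``states`` has shape ``(len(grid), dim)`` and rows past a divergence
    abort are NaN.
    """
    t0, t1 = grid[0], grid[-1]
    cuts = sorted({t0, t1, *(b for b in breakpoints if t0 < b < t1)})
    bound = opts.divergence_bound

    def blowup(t, y):
        return bound - np.max(np.abs(y))

    blowup.terminal = True
    blowup.direction = -1

    dim = len(y0)
    out = np.full((grid.size, dim), np.nan)
    out[0] = y0
    y = np.asarray(y0, dtype=float)
    diverged = False
    t_div = None
    dense = [] if want_dense else None
    for a, b in zip(cuts, cuts[1:]):
        t_eval = grid[(grid > a) & (grid <= b)]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method=opts.method,
            rtol=opts.rtol,
            atol=opts.atol,
            t_eval=t_eval if t_eval.size else None,
            events=blowup,
            max_step=opts.max_step,
            dense_output=want_dense,
        )
        if sol.status == -1:
            raise SolverError(f"integration failed on [{a}, {b}]: {sol.message}")
        if t_eval.size:
            idx = np.searchsorted(grid, sol.t)
            out[idx] = sol.y.T
        if want_dense and sol.sol is not None:
            dense.append(sol.sol)
        if sol.status == 1:  # divergence event fired
            diverged = True
            t_div = float(sol.t_events[0][0])
            break
        y = sol.y[:, -1] if sol.y.size else y
    return out, diverged, t_div, dense


# ---------------------------------------------------------------------------
# layer simulation
# ---------------------------------------------------------------------------


def simulate_full(
    network: ReactionNetwork,
    horizon,
    opts: SolverOptions = SolverOptions(),
) -> LayerTrajectory:
    """Direct simulation of the complete network ODE (absolute state)."""
    grid = _time_grid(horizon, opts.n_grid)

    def rhs(t, x):
        return network.S @ network.rates(x, t)

    states, div, t_div, dense = _integrate(
        rhs, network.x0, grid, network.input_breakpoints(), opts, want_dense=True
    )
    return LayerTrajectory(
        target=("full",),
        context=(),
        time_grid=grid,
        states=states,
        species=network.species,
        provenance="simulated",
        diverged=div,
        t_diverged=t_div,
        dense=dense,
    )


def simulate_isolated_layer(
    fs: FunctionalitySet,
    group,
    horizon,
    opts: SolverOptions = SolverOptions(),
) -> LayerTrajectory:
    """Isolated dynamics ``L(F | F^0)`` of a functionality group.

    For a group of several functionalities this is the layer of the extended
    network built from the union of their reaction sets.
    """
    net = fs.network
    g = fs.group(group)
    SF = restrict_stoichiometry(net, fs.reactions_of(g))
    grid = _time_grid(horizon, opts.n_grid)
    x0 = net.x0

    def rhs(t, y):
        return SF @ net.rates(x0 + y, t)

    states, div, t_div, dense = _integrate(
        rhs, np.zeros(net.n_species), grid, net.input_breakpoints(), opts,
        want_dense=True,
    )
    return LayerTrajectory(
        target=fs.group_names(g),
        context=(),
        time_grid=grid,
        states=states,
        species=net.species,
        provenance="simulated",
        diverged=div,
        t_diverged=t_div,
        dense=dense,
    )


def simulate_conditional_layer(
    fs: FunctionalitySet,
    new_group,
    context_group,
    horizon,
    opts: SolverOptions = SolverOptions(),
    upstream: LayerTrajectory | None = None,
    omit_altered: Iterable[str] = (),
    omit_species: Iterable[str] = (),
) -> LayerTrajectory:
    """Conditional dynamics ``L(F_new | F^0, context)``.

    By default the context's own (isolated-union) layer is integrated jointly
    with the new layer, avoiding interpolation error.  When
    ``opts.interpolate_upstream`` is set and ``upstream`` holds the context
    group's trajectory, the context state is instead replayed through a
    monotone cubic interpolant as a time-dependent input; the two modes agree
    within a small multiple of the solver tolerance.

    ``omit_altered`` names context reactions whose altered-rate contribution
    is forced to zero, and ``omit_species`` names species rows excluded from
    the layer (both as certified by the model-reduction module).
    """
    net = fs.network
    new = fs.group(new_group)
    ctx = fs.group(context_group)
    grid = _time_grid(horizon, opts.n_grid)
    x0 = net.x0
    n = net.n_species

    R_ctx = fs.reactions_of(ctx) if ctx else frozenset()
    R_all = fs.reactions_of(new | ctx)
    S_ctx = restrict_stoichiometry(net, R_ctx)
    S_all = restrict_stoichiometry(net, R_all)

    omit_idx = [net.reaction_index(r) for r in omit_altered]
    for r in omit_altered:
        if r not in R_ctx:
            raise ValueError(f"omitted altered reaction {r!r} is not a context reaction")
    keep_row = np.ones(n)
    for s in omit_species:
        keep_row[net.species_index(s)] = 0.0

    def new_rhs(t, xc, xn):
        v_full = net.rates(x0 + xc + xn, t)
        v_base = net.rates(x0 + xc, t)
        if omit_idx:
            v_full = v_full.copy()
            v_full[omit_idx] = v_base[omit_idx]
        return keep_row * (S_all @ v_full - S_ctx @ v_base)

    if not ctx:
        # empty context: reduces to the isolated layer of the new group
        def rhs(t, y):
            return new_rhs(t, np.zeros(n), y)

        y0 = np.zeros(n)
        states, div, t_div, _ = _integrate(rhs, y0, grid, net.input_breakpoints(), opts)
        xn = states
    elif opts.interpolate_upstream:
        if upstream is None:
            raise ValueError("interpolation mode needs the upstream trajectory")
        if not np.array_equal(upstream.time_grid, grid):
            raise GridMismatchError("upstream trajectory is not on the shared grid")

        def rhs(t, y):
            return new_rhs(t, upstream.interpolate(t), y)

        states, div, t_div, _ = _integrate(
            rhs, np.zeros(n), grid, net.input_breakpoints(), opts
        )
        xn = states
        div = div or upstream.diverged
        t_div = _min_opt(t_div, upstream.t_diverged)
    else:

        def rhs(t, y):
            xc, xn_ = y[:n], y[n:]
            dxc = S_ctx @ net.rates(x0 + xc, t)
            return np.concatenate([dxc, new_rhs(t, xc, xn_)])

        states, div, t_div, _ = _integrate(
            rhs, np.zeros(2 * n), grid, net.input_breakpoints(), opts
        )
        xn = states[:, n:]

    return LayerTrajectory(
        target=fs.group_names(new),
        context=fs.group_names(ctx),
        time_grid=grid,
        states=xn,
        species=net.species,
        provenance="simulated",
        diverged=div,
        t_diverged=t_div,
    )


def conditional_via_difference(
    fs: FunctionalitySet,
    new_group,
    context_group,
    horizon,
    opts: SolverOptions = SolverOptions(),
) -> LayerTrajectory:
    """``L(F_new | ctx)`` as ``L(ctx u new | F^0) - L(ctx | F^0)``.

    Serves as the independent oracle for :func:`simulate_conditional_layer`.
    """
    net = fs.network
    new = fs.group(new_group)
    ctx = fs.group(context_group)
    grid = _time_grid(horizon, opts.n_grid)
    joint = simulate_isolated_layer(fs, new | ctx, horizon, opts)
    if ctx:
        base = simulate_isolated_layer(fs, ctx, horizon, opts)
    else:
        base = LayerTrajectory(
            target=("F0",),
            context=(),
            time_grid=grid,
            states=np.zeros((grid.size, net.n_species)),
            species=net.species,
            provenance="constant_zero_layer",
        )
    out = joint - base
    return out.relabel(
        target=fs.group_names(new),
        context=fs.group_names(ctx),
        provenance="derived_difference",
    )


def altered_rates(
    network: ReactionNetwork, base_state, increment, t: float = 0.0
) -> np.ndarray:
    """Altered-reaction rates ``v(base + increment, t) - v(base, t)``."""
    base = np.asarray(base_state, dtype=float)
    inc = np.asarray(increment, dtype=float)
    return network.rates(base + inc, t, check=True) - network.rates(base, t, check=True)


def simulate_noncascaded(
    fs: FunctionalitySet,
    partition: Sequence[Iterable[str]] | None = None,
    horizon=None,
    opts: SolverOptions = SolverOptions(),
) -> list[LayerTrajectory]:
    """Non-cascaded layering of a strict partition, integrated simultaneously.

    Each layer's dynamics see the sum of all layers' states, so the sum of
    layer states (plus ``x0``) reproduces the full network trajectory.  The
    partition defaults to the functionality set itself, which must then be a
    strict partition (overlap is only allowed in cascaded mode).
    """
    net = fs.network
    if partition is None:
        groups = [f.reactions for f in fs.functionalities]
        names = [(f.name,) for f in fs.functionalities]
    else:
        groups = [frozenset(g) for g in partition]
        names = [(f"P{i + 1}",) for i in range(len(groups))]
    if not fs.is_partition(groups):
        raise PartitionError(
            "non-cascaded layering requires a strict partition of the reaction set"
        )
    mats = [restrict_stoichiometry(net, g) for g in groups]
    grid = _time_grid(horizon, opts.n_grid)
    n, m = net.n_species, len(groups)
    x0 = net.x0

    def rhs(t, y):
        layers = y.reshape(m, n)
        total = x0 + layers.sum(axis=0)
        v = net.rates(total, t)
        return np.concatenate([Sl @ v for Sl in mats])

    states, div, t_div, _ = _integrate(
        rhs, np.zeros(m * n), grid, net.input_breakpoints(), opts
    )
    out = []
    for i in range(m):
        out.append(
            LayerTrajectory(
                target=names[i],
                context=tuple(x for j, nm in enumerate(names) if j != i for x in nm),
                time_grid=grid,
                states=states[:, i * n : (i + 1) * n],
                species=net.species,
                provenance="simulated",
                diverged=div,
                t_diverged=t_div,
            )
        )
    return out


def reconstruct_absolute(
    trajectories: Sequence[LayerTrajectory], x0: np.ndarray
) -> np.ndarray:
    """Absolute state ``x0 + sum of layer states`` on the shared grid."""
    total = np.full_like(trajectories[0].states, 0.0) + np.asarray(x0)
    for tr in trajectories:
        trajectories[0]._check_grid(tr)
        total = total + tr.states
    return total


# ---------------------------------------------------------------------------
# mixed layer structure with a control layer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ControlLayer:
    """A non-cascaded control subsystem (e.g. cofactor pools).

    The control layer holds a subset of species and the reactions exclusive to
    it.  It receives the control-species production/consumption rates of every
    cascaded layer and broadcasts the current control-species concentrations
    to all of them.  Control reactions must be disjoint from every cascaded
    functionality and must only move control species.
    """

    species: frozenset[str]
    reactions: frozenset[str] = frozenset()

    def validate(self, fs: FunctionalitySet):
        net = fs.network
        for s in self.species:
            net.species_index(s)
        net.check_reaction_ids(self.reactions)
        for f in fs.functionalities:
            shared = f.reactions & self.reactions
            if shared:
                raise StructureError(
                    f"control reactions {sorted(shared)} overlap functionality {f.name!r}"
                )
        # control reactions may only change control species
        idx = [net.species_index(s) for s in net.species if s not in self.species]
        for rid in self.reactions:
            col = net.S[:, net.reaction_index(rid)]
            if idx and np.any(col[idx] != 0):
                raise StructureError(
                    f"control reaction {rid!r} changes non-control species"
                )


def simulate_with_control_layer(
    fs: FunctionalitySet,
    control: ControlLayer,
    order: Sequence[int | str] | None = None,
    horizon=None,
    opts: SolverOptions = SolverOptions(),
) -> tuple[list[LayerTrajectory], LayerTrajectory]:
    """Cascade the functionalities while a control layer runs alongside.

    Cascaded layers carry only non-control species (control-species rows of
    their restricted stoichiometries are zeroed); the control layer integrates
    the control-species rows over *all* reactions, i.e. it receives every
    layer's cofactor flux plus its own exclusive reactions.  The sum of all
    cascade states, the control state and ``x0`` reproduces the full model.
    """
    net = fs.network
    control.validate(fs)
    if order is None:
        order = list(range(fs.n_layers))
    order = [fs.index(k) for k in order]
    if sorted(order) != list(range(fs.n_layers)):
        raise ValueError("order must be a permutation of all functionalities")

    # all reactions must be either in a functionality or exclusive to control
    casc_rxns = fs.reactions_of(range(fs.n_layers))
    uncovered = set(net.reaction_ids) - set(casc_rxns) - set(control.reactions)
    if uncovered:
        raise StructureError(f"reactions outside cascade and control: {sorted(uncovered)}")

    n = net.n_species
    Q = np.zeros(n)  # control-species row mask
    for s in control.species:
        Q[net.species_index(s)] = 1.0
    P = 1.0 - Q

    # cumulative cascade matrices with control rows removed
    prefixes = []
    for i in range(len(order)):
        R = fs.reactions_of(order[: i + 1])
        prefixes.append(P[:, None] * restrict_stoichiometry(net, R))
    S_control = Q[:, None] * net.S  # control rows over every reaction

    grid = _time_grid(horizon, opts.n_grid)
    m = len(order)
    x0 = net.x0

    def rhs(t, y):
        layers = y[: m * n].reshape(m, n)
        z = y[m * n :]
        cum = np.cumsum(layers, axis=0)
        zfull = Q * z
        # absolute state seen by the prefix ending at layer i (all read z)
        outs = []
        v_prev = None
        prev = np.zeros(n)
        for i in range(m):
            v_i = net.rates(x0 + zfull + cum[i], t)
            d = prefixes[i] @ v_i - (prefixes[i - 1] @ v_prev if i else 0.0)
            outs.append(d)
            v_prev = v_i
            prev = cum[i]
        v_total = net.rates(x0 + zfull + cum[-1], t)
        dz = S_control @ v_total
        return np.concatenate([np.concatenate(outs), dz])

    states, div, t_div, _ = _integrate(
        rhs, np.zeros((m + 1) * n), grid, net.input_breakpoints(), opts
    )
    casc = []
    for i, fi in enumerate(order):
        casc.append(
            LayerTrajectory(
                target=(fs.functionalities[fi].name,),
                context=tuple(fs.functionalities[k].name for k in order[:i]),
                time_grid=grid,
                states=states[:, i * n : (i + 1) * n],
                species=net.species,
                provenance="simulated",
                diverged=div,
                t_diverged=t_div,
            )
        )
    ctrl = LayerTrajectory(
        target=("control",),
        context=tuple(fs.names),
        time_grid=grid,
        states=states[:, m * n :] * Q,
        species=net.species,
        provenance="simulated",
        diverged=div,
        t_diverged=t_div,
    )
    return casc, ctrl
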