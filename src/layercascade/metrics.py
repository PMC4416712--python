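"""Interaction metrics between functionality groups.

Mutual dynamics ``M(A; B | ctx) = L(A|ctx) + L(B|ctx) - L(A,B|ctx)`` is the
error of approximating the joint dynamics by the sum of the two groups'
conditional dynamics -- a symmetric, time-varying vector measure of
interdependence.  From it derive, pointwise in time with a weighted Euclidean
norm over species:

* incompatibility ``I = ||M|| / ||L(A|ctx) + L(B|ctx)||`` (interaction
  strength, >= 0);
* cooperativity ``C = -<M, L_A + L_B> / (||M|| ||L_A + L_B||)``, the cosine of
  the angle between ``-M`` and the summed conditional dynamics (interaction
  direction: -1 attenuation, +1 amplification, 0 orthogonal effects).

Both are 0/0 at ``t = 0`` by construction (all layer states start at zero);
time points where a norm falls below a relative floor are *masked*, never
reported as NaN or infinity, and excluded from time averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import numpy.ma as ma
import pandas as pd

from .errors import UndefinedAverageError, WeightError
from .graph import LayeringGraph
from .layers import LayerTrajectory

__all__ = [
    "mutual_dynamics",
    "mutual_dynamics_via_conditional",
    "incompatibility_series",
    "cooperativity_series",
    "time_average",
    "InteractionProfile",
    "interaction_profile",
    "interaction_matrix",
    "is_unstable",
]

#: Relative floor under which a norm counts as degenerate (times the running
#: maximum of that norm over the trajectory so far).
EPS_REL = 1e-12


def _weights(weights, species) -> np.ndarray:
    if weights is None:
        return np.ones(len(species))
    if isinstance(weights, dict):
        w = np.array([float(weights.get(s, 1.0)) for s in species])
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (len(species),):
        raise WeightError("need one weight per species")
    if np.any(w < 0):
        raise WeightError("weights must be non-negative")
    return w


def _wnorm(states: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.sqrt(np.nansum(w * states**2, axis=1))


def mutual_dynamics(g: LayeringGraph, A, B, context=()) -> LayerTrajectory:
    """``M(A; B | ctx)`` via the symmetric sum route.

    ``L(A|ctx) + L(B|ctx) - L(A,B|ctx)``; exactly symmetric in (A, B) because
    the arithmetic is identical either way.
    """
    fs = g.fs
    a, b = fs.group(A), fs.group(B)
    ctx = fs.group(context) if context else frozenset()
    M = g.conditional(a, ctx) + g.conditional(b, ctx) - g.conditional(a | b, ctx)
    return M.relabel(
        target=fs.group_names(a) + fs.group_names(b),
        context=fs.group_names(ctx),
        provenance="mutual_dynamics",
    )


def mutual_dynamics_via_conditional(g: LayeringGraph, A, B, context=()) -> LayerTrajectory:
    """Second route ``L(B|ctx) - L(B|A,ctx)``; agrees with the sum route."""
    fs = g.fs
    a, b = fs.group(A), fs.group(B)
    ctx = fs.group(context) if context else frozenset()
    M = g.conditional(b, ctx) - g.conditional(b, a | ctx)
    return M.relabel(provenance="mutual_dynamics")


def _degenerate_mask(norm: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """True where the norm is degenerate relative to its running maximum."""
    n = np.where(valid, norm, 0.0)
    runmax = np.maximum.accumulate(n)
    return (runmax <= 0.0) | (n < EPS_REL * runmax)


def incompatibility_series(
    M: LayerTrajectory, LA: LayerTrajectory, LB: LayerTrajectory, weights=None
) -> ma.MaskedArray:
    """Per-time incompatibility ``I(t)``; masked where the denominator vanishes."""
    M._check_grid(LA)
    M._check_grid(LB)
    w = _weights(weights, M.species)
    s = LA.states + LB.states
    n_m = _wnorm(M.states, w)
    n_s = _wnorm(s, w)
    valid = M.valid_mask & LA.valid_mask & LB.valid_mask
    mask = ~valid | _degenerate_mask(n_s, valid)
    vals = np.divide(n_m, n_s, out=np.zeros_like(n_m), where=~mask)
    return ma.MaskedArray(vals, mask=mask)


def cooperativity_series(
    M: LayerTrajectory, LA: LayerTrajectory, LB: LayerTrajectory, weights=None
) -> ma.MaskedArray:
    """Per-time cooperativity ``C(t)``; masked where either norm vanishes."""
    M._check_grid(LA)
    M._check_grid(LB)
    w = _weights(weights, M.species)
    s = LA.states + LB.states
    n_m = _wnorm(M.states, w)
    n_s = _wnorm(s, w)
    valid = M.valid_mask & LA.valid_mask & LB.valid_mask
    mask = ~valid | _degenerate_mask(n_s, valid) | _degenerate_mask(n_m, valid)
    dot = np.nansum(w * M.states * s, axis=1)
    vals = np.divide(-dot, n_m * n_s, out=np.zeros_like(dot), where=~mask)
    np.clip(vals, -1.0, 1.0, out=vals)  # guard rounding at |C| = 1
    return ma.MaskedArray(vals, mask=mask)


def time_average(series, time_grid=None, mask=None) -> float:
    """Trapezoidal time average over the unmasked sub-horizon.

    ``integral(series) / Delta_T`` with both taken over the unmasked grid
    points only; needs at least two of them.
    """
    if isinstance(series, ma.MaskedArray):
        m = ma.getmaskarray(series)
        vals = series.data
    else:
        vals = np.asarray(series, dtype=float)
        m = np.zeros(vals.shape, dtype=bool) if mask is None else np.asarray(mask)
    if time_grid is None:
        raise ValueError("time_grid is required")
    t = np.asarray(time_grid, dtype=float)
    keep = ~m
    if keep.sum() < 2:
        raise UndefinedAverageError("fewer than two unmasked grid points")
    tt, vv = t[keep], vals[keep]
    dt = tt[-1] - tt[0]
    return float(np.trapezoid(vv, tt) / dt)


@dataclass
class InteractionProfile:
    """Mutual dynamics and derived scalars for one pair in one context."""

    pair: tuple[tuple[str, ...], tuple[str, ...]]
    context: tuple[str, ...]
    time_grid: np.ndarray
    M: LayerTrajectory
    I: ma.MaskedArray
    C: ma.MaskedArray
    I_avg: float | None
    C_avg: float | None
    weights: np.ndarray

    def end_values(self) -> tuple[float | None, float | None]:
        """(I, C) at the last defined grid point (None if fully masked)."""
        out = []
        for series in (self.I, self.C):
            idx = np.flatnonzero(~ma.getmaskarray(series))
            out.append(float(series.data[idx[-1]]) if idx.size else None)
        return tuple(out)


def interaction_profile(
    g: LayeringGraph, A, B, context=(), weights=None
) -> InteractionProfile:
    """Full interaction profile ``M, I(t), C(t), <I>, <C>`` for a pair."""
    fs = g.fs
    a, b = fs.group(A), fs.group(B)
    ctx = fs.group(context) if context else frozenset()
    LA = g.conditional(a, ctx)
    LB = g.conditional(b, ctx)
    M = mutual_dynamics(g, a, b, ctx)
    w = _weights(weights, fs.network.species)
    I = incompatibility_series(M, LA, LB, w)
    C = cooperativity_series(M, LA, LB, w)
    grid = M.time_grid

    def _avg(series):
        try:
            return time_average(series, grid)
        except UndefinedAverageError:
            return None

    return InteractionProfile(
        pair=(fs.group_names(a), fs.group_names(b)),
        context=fs.group_names(ctx),
        time_grid=grid,
        M=M,
        I=I,
        C=C,
        I_avg=_avg(I),
        C_avg=_avg(C),
        weights=w,
    )


def is_unstable(
    tr: LayerTrajectory, slope_tol: float = 1e-3, states: np.ndarray | None = None
) -> bool:
    """Operational stability call: diverged, or still moving at the end.

    A trajectory is unstable if integration hit the divergence bound, or if
    the relative end-slope ``||dx/dt|| / (1 + ||x||)`` estimated from the last
    two valid grid points exceeds ``slope_tol``.
    """
    if tr.diverged:
        return True
    X = tr.states if states is None else states
    valid = ~np.any(np.isnan(X), axis=1)
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return True
    i0, i1 = idx[-2], idx[-1]
    dt = tr.time_grid[i1] - tr.time_grid[i0]
    slope = np.linalg.norm(X[i1] - X[i0]) / dt
    return bool(slope / (1.0 + np.linalg.norm(X[i1])) > slope_tol)


def _converged(series: ma.MaskedArray, grid: np.ndarray, tol: float = 1e-4) -> bool:
    """Relative change of the series over the last 5% of the horizon < tol."""
    mask = ma.getmaskarray(series)
    t_cut = grid[0] + 0.95 * (grid[-1] - grid[0])
    keep = (~mask) & (grid >= t_cut)
    if keep.sum() < 2:
        return False
    tail = series.data[keep]
    scale = max(abs(tail[-1]), 1e-12)
    return bool((tail.max() - tail.min()) / scale < tol)


def _category(sum_unstable: bool, mutual_unstable: bool, total_unstable: bool) -> str:
    if not sum_unstable and not mutual_unstable:
        return "context_unstable" if total_unstable else "all_stable"
    if sum_unstable and mutual_unstable:
        return "partially_stabilised" if total_unstable else "interaction_stabilises"
    if sum_unstable and not mutual_unstable and not total_unstable:
        return "stabilised_by_one"
    return "other"


def interaction_matrix(
    g: LayeringGraph,
    weights=None,
    pairs=None,
    slope_tol: float = 1e-3,
    convergence_tol: float = 1e-4,
) -> pd.DataFrame:
    """End-of-horizon I/C for every pair in every context, with stability labels.

    One row per unordered functionality pair and per context subset of the
    remaining functionalities: ``C(N_L, 2) * 2^(N_L - 2)`` rows in total.
    ``I_end``/``C_end`` are the values at the last defined grid point together
    with a convergence flag (the underlying trajectories may diverge even when
    I and C converge, so convergence is assessed on I/C themselves).  The
    stability columns flag whether the summed conditional dynamics, the mutual
    dynamics and the overall network trajectory are unstable, and ``category``
    condenses them into the standard interaction classes (e.g. an unstable sum
    with a stable total means the interaction stabilises the network).
    """
    fs = g.fs
    n = fs.n_layers
    full = None
    rows = []
    if pairs is None:
        pairs = list(combinations(range(n), 2))
    for (i, j) in pairs:
        rest = [k for k in range(n) if k not in (i, j)]
        for csize in range(len(rest) + 1):
            for ctx in combinations(rest, csize):
                prof = interaction_profile(g, i, j, frozenset(ctx), weights)
                LA = g.conditional({i}, frozenset(ctx))
                LB = g.conditional({j}, frozenset(ctx))
                Lsum = LA + LB
                I_end, C_end = prof.end_values()
                if full is None:
                    full = g.path_reconstruction()
                sum_un = is_unstable(Lsum, slope_tol)
                mut_un = is_unstable(prof.M, slope_tol)
                tot_un = is_unstable(prof.M, slope_tol, states=full)
                no_interaction = I_end is None or (
                    ma.getdata(prof.I)[~ma.getmaskarray(prof.I)].max(initial=0.0)
                    < 1e-8
                )
                rows.append(
                    {
                        "pair_a": "+".join(prof.pair[0]),
                        "pair_b": "+".join(prof.pair[1]),
                        "context": "+".join(prof.context) if prof.context else "F0",
                        "I_end": I_end,
                        "C_end": C_end,
                        "I_avg": prof.I_avg,
                        "C_avg": prof.C_avg,
                        "I_converged": _converged(prof.I, prof.time_grid, convergence_tol),
                        "sum_unstable": sum_un,
                        "mutual_unstable": mut_un,
                        "total_unstable": tot_un,
                        "category": "no_interaction"
                        if no_interaction
                        else _category(sum_un, mut_un, tot_un),
                    }
                )
    return pd.DataFrame(rows)
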