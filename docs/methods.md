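# Methods

## Model class and layer semantics

The package works on deterministic mass-balance ODE models
`x' = S v(x, t)`, `x(0) = x0`, with concentrations in arbitrary consistent
units and time in the model's own unit. Rate laws are either sympy
expressions over species names, input-signal names and `t`, or opaque Python
callables; the engine never differentiates them symbolically. Stochastic
(SSA) semantics and parameter estimation are out of scope.

A *layer* is the incremental trajectory attributable to a functionality
group in a stated context. Layer states start at zero and are increments,
not concentrations: they legitimately go negative, and only the
reconstructed absolute state `x0 + Σ layers` is physically interpretable.
The reconstructed state is checked for plausibility nowhere — divergence and
negativity of layers are results, not errors.

Three equivalent routes to a conditional layer exist and are all
implemented because their agreement is the framework's main internal
consistency check: (i) direct integration of the conditional ODE with the
context integrated jointly, (ii) the same ODE with the context replayed from
a stored trajectory, (iii) the difference of two isolated union layers.
Route (i) is the default: it avoids interpolation error entirely. Route (ii)
exists for replaying persisted trajectories; it evaluates the context from
the solver's dense output when available and falls back to monotone cubic
(PCHIP) interpolation on the shared grid otherwise. Routes agree within a
small multiple of the solver tolerance in the test suite.

## Numerical choices

* **Solver**: `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
  automatic switching), `rtol = 1e-8`, `atol = 1e-10` by default; all
  configurable through `SolverOptions`.
* **Shared grid**: dense solutions are evaluated on a fixed uniform grid
  (default 1001 points over the horizon). All trajectory algebra and all
  metrics operate on this grid; mixing grids raises an error rather than
  silently resampling.
* **Input discontinuities**: piecewise-constant schedules contribute
  breakpoints at which integration restarts, so steps are never smoothed by
  the error controller.
* **Divergence**: integration aborts when the max-norm of the (stacked)
  state exceeds a bound (default 1e9). The trajectory is kept up to the
  abort time, later grid rows are blank (NaN internally, masked in every
  output), and the flag propagates through algebra; metrics are computed on
  the common valid sub-horizon. Diverging layers are meaningful results
  (an unstable subsystem is a finding), hence data, not failure.
* **Numerical rank** (`layer_dimension`): singular values below
  `1e-10 × σ_max` count as zero; configurable.
* **Trajectory identities**: tests compare trajectories at
  `10 × (rtol · scale + atol)` where `scale` is the magnitude of the states
  involved — the natural "10× solver tolerance" reading that stays
  meaningful for both small toy layers and diverging controller layers.

## The layering graph

Nodes are (target functionality, context subset) pairs; level `l` holds
`(N_L − l + 1)·C(N_L, l − 1)` nodes. For every non-empty subset of
functionalities exactly one member is integrated numerically
(`2^{N_L} − 1` integrations total) and the rest of the level follows from the
Bayes-rule identity, strictly level by level in deterministic order.

Which member of a subset to simulate is a free choice; we operationalise
"simulate the simplest layer" as: minimise first the number of species with
nonzero dynamics in the candidate layer (via the reachability certificate
below), then the number of active reactions (own plus non-prunable altered),
with ties broken by functionality index. The choice only affects efficiency,
never results.

Grouped (multi-functionality) nodes — needed for combined knock-outs and for
`L(A,B|ctx)` in the mutual dynamics — are assembled exactly from
single-target nodes along a chain, `L(A,B|C) = L(A|C) + L(B|A,C)`, and
cached. This is algebraically identical to simulating the union layer and
costs no integration; the deletion-resimulation oracle in the tests confirms
the assembled nodes against fresh simulations of the modified network.

Knock-out prediction: `−L(targets | all others)` is the change in the full
trajectory when the targets' *exclusive* reactions are removed; reactions
shared with remaining functionalities stay, which is exactly what the leaf
node encodes.

## Interaction metrics

`I` and `C` are ratios of weighted Euclidean norms over species (default
weight 1; weights of 0 are allowed to silence uninteresting intermediates,
and the scalar product in `C` is weighted consistently). Both are 0/0 at
`t = 0` by construction, and can degenerate later whenever a norm vanishes.
A time point is *masked* when the relevant norm falls below
`1e-12 ×` its running maximum (which also masks `t = 0`); masked points are
excluded from time averages and never surface as NaN or infinity. Time
averages are trapezoidal integrals over the unmasked sub-horizon divided by
its length, requiring at least two unmasked points.

"Steady-state" I/C in the interaction table are the values at the last
defined grid point, accompanied by a convergence flag (relative change over
the final 5 % of the horizon below 1e-4). Convergence is assessed on I and C
themselves, because they frequently converge while the underlying layer
trajectories diverge.

Stability labels in the interaction table need an operational criterion: a
trajectory counts as unstable if it hit the divergence bound or its relative
end slope `‖x'‖/(1+‖x‖)`, estimated from the last two valid grid points,
exceeds a threshold (default 1e-3). The five resulting categories (all
stable; context unstable; interaction stabilises; partially stabilised;
stabilised by one partner) follow from the three flags (sum of isolated
parts, mutual dynamics, total network); pairs whose mutual dynamics are
numerically zero are labelled "no interaction" before any classification.
This criterion is a package decision, and the threshold is exposed.

## Reduction certificates

The rate of a context reaction needs to be re-evaluated inside a layer only
if it depends on a species the layer can move — directly, or transitively
through the context's own species → rate → species structure. We compute the
boolean transitive closure of `I(S_ctx)·I(∂v/∂x)` applied to the species the
layer's own reactions move; for indicator matrices this closure has exactly
the zero pattern of the matrix exponential formulation (every walk of length
≤ dim is captured, and `exp(A) ≥ I`), so the closure is used as the default
route — exact and immune to overflow — while the literal
indicator-of-exponential evaluation is kept as an independent cross-check on
small instances. The condition is sufficient, not necessary, so pruning is
always sound, and because a certified-prunable rate receives bit-identical
arguments with or without the layer state, pruned and unpruned simulations
coincide exactly. Dependency patterns come from declared dependencies, the
free symbols of symbolic rate laws, or — for opaque callables — numerical
probing at 5 random positive states with relative perturbation 1e-6 and
change threshold 1e-12 (declared information always wins). Pruning is
advisory (a report) unless omissions are passed explicitly to the simulator.

## Synthetic networks

The generator emulates the package's input class for download-free testing:
random sparse stoichiometries over a configurable mix of zero-order,
first-order, bimolecular mass-action and Michaelis–Menten kinetics (defaults
0.2/0.4/0.2/0.2), rate constants in [0.2, 1], Michaelis constants in
[0.5, 2], initial concentrations in [0.5, 2], and a round-robin functionality
cover that is a strict partition at `overlap_fraction = 0` and overlapping
above it. No generated reaction is autocatalytic, so trajectories grow at
most linearly and identity suites integrate cleanly; a `disconnect_blocks`
mode confines each functionality to its own species pool to create provably
non-interacting pairs. Identical specs are bit-reproducible.

What this does *not* emulate: conservation laws typical of signalling cycles,
wide timescale separation, oscillatory attractors, and realistic parameter
correlations. Passing identity and soundness tests on this corpus therefore
demonstrates correctness of the layer algebra and certificates, not
biological fidelity of any particular model; the controller fixture covers
the qualitatively hard regime (saturation-driven instability and integral
feedback) that the random corpus avoids.

Test and acceptance runs use 201 grid points over a horizon of 3 time units
for the random corpus and 501 points over 500 time units for the controller
fixture — sizes at which every identity already stresses the full code path.

## The controller fixture

Four species (two pathway intermediates, two controller species), nine
reactions, with the two observation rates duplicated into pathway-facing and
controller-facing copies so the two roles occupy separate stoichiometric
columns. Michaelis–Menten steps `V_i(x) = k_i x/(m_i + x)` and
non-competitive inhibition factors `1/(p + x)` close two integral feedback
loops: controller A observes the first intermediate and throttles its
production; controller B observes the second and throttles the conversion.

Parameters are package defaults chosen to realise the intended regime, not
values taken from any external source: the consumption steps of both
controller species operate near saturation (`m = 0.01`, giving integral
action), the conversion and removal of the first intermediate saturate below
the stepped production rate (instability of the uncontrolled pathway for
`k = 10`), and the analytic `k = 3` steady state sits near
`(y1, y2, a, b) = (1, 1, 0.8, 1.5)`. The exact initial state is obtained by
a Newton solve of the full steady-state system at `k = 3` before the input
steps to `k = 10` at `t = 50`. With these defaults the isolated pathway
layer diverges at constant slope, the assembled model adapts perfectly, and
the pathway–controller pair shows the cancellation signature
`I → 1`, `C → −1`.

## Mixed (control-layer) structures

Cofactor-like species can be lifted out of the cascade: their rows are
removed from every cascaded layer's stoichiometry and collected — over all
reactions, plus the control layer's exclusive reactions — into one
non-cascaded control state that every layer reads. Control reactions must be
disjoint from all functionalities and may only move control species; under
that contract the summed system is algebraically identical to the full
model, which the tests verify against direct simulation. Reversible
reactions stay single signed-rate columns throughout the package.

## SBML scope

Import supports Level 2/3 core: compartments (sizes become constants),
species (boundary/constant species are frozen at their initial value and
dropped from `S`), global and local parameters, function definitions
(inlined), kinetic laws in content MathML, and assignment rules that reduce
to pure functions of time (imported as input signals). Events, algebraic and
rate rules, delays, stoichiometry math and state-dependent assignment rules
raise an explicit unsupported-feature error — nothing is dropped silently.
Export writes Level 3 Version 2 and requires symbolic rate laws; piecewise
input schedules become assignment rules over csymbol time. The ODE
convention is the plain stoichiometric form; models whose kinetic laws embed
a volume factor are imported as written with the size substituted.

## Known limitations

* The omission certificate is structural; rates that are numerically but not
  structurally independent are not pruned.
* Interpolated-upstream replay of *derived* (algebra-only) trajectories
  falls back to grid interpolation and inherits its error.
* The stability classification depends on the end-slope threshold; slowly
  converging systems near the threshold can be mislabelled — lengthen the
  horizon or tighten the threshold in that case.
* Metrics on diverged pairs are reported on the common valid sub-horizon
  only; comparing pairs with different valid horizons compares different
  time windows.
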