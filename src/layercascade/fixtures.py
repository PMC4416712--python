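"""Built-in example models.

* :func:`birth_death_model` -- the one-species birth-death toy whose layer
  algebra has closed forms (the oracle network for the metric definitions).
* :func:`controller_model` -- a four-species pathway with two integral
  feedback motifs achieving perfect adaptation; the pathway alone goes
  unstable after a step in its production rate, the first controller
  stabilises it, the second destabilises it slightly.
* :func:`two_pathway_input_schedule` -- the piecewise-constant two-input
  switching schedule used in the crosstalk example.
"""

from __future__ import annotations

import numpy as np
import sympy as sp
from scipy.optimize import fsolve

from .errors import EquilibrationError
from .network import (
    Functionality,
    FunctionalitySet,
    InputSignal,
    RateLaw,
    Reaction,
    ReactionNetwork,
    mass_action,
)

__all__ = [
    "birth_death_model",
    "controller_model",
    "CONTROLLER_DEFAULTS",
    "two_pathway_input_schedule",
]


def birth_death_model(rate_in: float = 1.0, rate_out: float = 1.0):
    """One species X: R1 = constant birth, R2 = first-order death, x0 = 0.

    With unit rates the closed forms are ``L(F1)(t) = t`` (birth alone),
    ``L(F1, F2)(t) = 1 - exp(-t)`` (full model), hence
    ``L(F2 | F1)(t) = 1 - exp(-t) - t`` and
    ``M(F1; F2)(t) = t - 1 + exp(-t)``.
    """
    net = ReactionNetwork(
        species=["X"],
        x0=[0.0],
        reactions=[
            Reaction("R1", {"X": 1.0}, mass_action(rate_in)),
            Reaction("R2", {"X": -1.0}, mass_action(rate_out, {"X": 1})),
        ],
        name="birth_death",
    )
    fs = FunctionalitySet(
        net, [Functionality("F1", {"R1"}), Functionality("F2", {"R2"})]
    )
    return net, fs


#: Default kinetic parameters of the perfect-adaptation controller fixture.
#: Chosen so that the k=3 steady state is (y1, y2, a, b) ~ (1, 1, 0.8, 1.5),
#: the Y1-removing reactions saturate below the stepped production rate
#: (instability of the isolated pathway), and the controller consumption
#: steps V_-a, V_-b operate near saturation (integral action).
CONTROLLER_DEFAULTS = {
    "k1": 6.0,  # Vmax of the Y1 -> Y2 conversion V1
    "m1": 0.5,
    "k2": 2.0,  # Vmax of the Y2 consumption V2
    "m2": 1.0,
    "k_va": 2.0,  # Vmax of the observation reaction Va(y1)
    "m_va": 1.0,
    "k_ma": 1.0,  # Vmax of the controller consumption V-a(a)
    "m_ma": 0.01,  # small: V-a near saturation
    "k_vb": 2.0,
    "m_vb": 1.0,
    "k_mb": 1.0,
    "m_mb": 0.01,
    "p_a": 0.2,  # phi_a(a) = 1 / (p_a + a) inhibits Y1 production
    "p_b": 0.5,  # phi_b(b) = 1 / (p_b + b) inhibits the Y1 -> Y2 conversion
}


def controller_model(
    params: dict | None = None,
    k_base: float = 3.0,
    k_step: float = 10.0,
    t_step: float = 50.0,
):
    """The two-controller perfect-adaptation network.

    Species ``y1, y2`` (pathway intermediates) and ``a, b`` (controller
    states).  Nine reactions; the observation steps ``Va`` and ``Vb`` each
    appear twice with the same rate -- one copy drains the pathway species,
    the other feeds the controller species -- so pathway and controller
    effects separate into different stoichiometric columns::

        S =  [ 1 -1  0 -1  0  0  0  0  0 ]   (y1)
             [ 0  1 -1  0  0  0 -1  0  0 ]   (y2)
             [ 0  0  0  0  1 -1  0  0  0 ]   (a)
             [ 0  0  0  0  0  0  0  1 -1 ]   (b)

    Functionalities: F1 = uncontrolled pathway (columns 1-4 and 7),
    F2 = first controller (columns 5, 6), F3 = second controller (8, 9).
    The input ``k(t)`` steps from ``k_base`` to ``k_step`` at ``t_step``;
    the initial state is the numerically equilibrated ``k = k_base`` steady
    state of the full model.
    """
    p = dict(CONTROLLER_DEFAULTS)
    if params:
        p.update(params)
    if any(v <= 0 for v in p.values()):
        raise ValueError("controller parameters must be positive")

    y1, y2, a, b, k = sp.symbols("y1 y2 a b k")

    def V(vmax, m, x):
        return vmax * x / (m + x)

    rates = {
        "R1": k / (p["p_a"] + a),
        "R2": V(p["k1"], p["m1"], y1) / (p["p_b"] + b),
        "R3": V(p["k2"], p["m2"], y2),
        "R4": V(p["k_va"], p["m_va"], y1),
        "R5": V(p["k_va"], p["m_va"], y1),
        "R6": V(p["k_ma"], p["m_ma"], a),
        "R7": V(p["k_vb"], p["m_vb"], y2),
        "R8": V(p["k_vb"], p["m_vb"], y2),
        "R9": V(p["k_mb"], p["m_mb"], b),
    }
    stoich = {
        "R1": {"y1": 1.0},
        "R2": {"y1": -1.0, "y2": 1.0},
        "R3": {"y2": -1.0},
        "R4": {"y1": -1.0},
        "R5": {"a": 1.0},
        "R6": {"a": -1.0},
        "R7": {"y2": -1.0},
        "R8": {"b": 1.0},
        "R9": {"b": -1.0},
    }

    x0 = _equilibrate(p, k_base)
    net = ReactionNetwork(
        species=["y1", "y2", "a", "b"],
        x0=x0,
        reactions=[Reaction(rid, stoich[rid], RateLaw(expr=rates[rid])) for rid in rates],
        inputs=[InputSignal("k", schedule=[(0.0, t_step, k_base), (t_step, None, k_step)])],
        name="adaptation_controller",
    )
    fs = FunctionalitySet(
        net,
        [
            Functionality("F1", {"R1", "R2", "R3", "R4", "R7"}),
            Functionality("F2", {"R5", "R6"}),
            Functionality("F3", {"R8", "R9"}),
        ],
    )
    return net, fs


def _equilibrate(p: dict, k: float) -> np.ndarray:
    """Steady state of the full controller model at constant input ``k``."""

    def F(x):
        y1, y2, a, b = x
        v1 = p["k1"] * y1 / (p["m1"] + y1) / (p["p_b"] + b)
        va = p["k_va"] * y1 / (p["m_va"] + y1)
        vb = p["k_vb"] * y2 / (p["m_vb"] + y2)
        return [
            k / (p["p_a"] + a) - v1 - va,
            v1 - p["k2"] * y2 / (p["m2"] + y2) - vb,
            va - p["k_ma"] * a / (p["m_ma"] + a),
            vb - p["k_mb"] * b / (p["m_mb"] + b),
        ]

    guess = np.array([1.0, 1.0, 0.8, 1.5])
    sol, info, ier, msg = fsolve(F, guess, full_output=True)
    if ier != 1 or np.any(sol <= 0) or np.max(np.abs(F(sol))) > 1e-9:
        raise EquilibrationError(f"steady-state solve failed: {msg}")
    return np.asarray(sol, dtype=float)


def two_pathway_input_schedule() -> tuple[InputSignal, InputSignal]:
    """Two-input switching schedule (off/off, on/off, on/on, off/on, on/on).

    ``S1`` and ``S2`` switch between 0 and 5 at t = 20, 40, 80, 100; the dwell
    times are long enough for a signalling cascade to settle between switches.
    """
    s1 = InputSignal(
        "S1",
        schedule=[(0, 20, 0.0), (20, 40, 5.0), (40, 80, 5.0), (80, 100, 0.0), (100, None, 5.0)],
    )
    s2 = InputSignal(
        "S2",
        schedule=[(0, 20, 0.0), (20, 40, 0.0), (40, 80, 5.0), (80, 100, 5.0), (100, None, 5.0)],
    )
    return s1, s2
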