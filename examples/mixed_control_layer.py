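"""A mixed layer structure: cascaded functionalities plus a control layer.

Cofactor-like species (here a single pool E consumed by both functionalities
and replenished by an exclusive control reaction) are lifted out of the
cascade into a control layer that receives every layer's cofactor flux and
broadcasts the current pool level back.  The sum of cascade states, control
state and x0 still reproduces the full model exactly.
"""

import numpy as np

import layercascade as lc

rxns = [
    lc.Reaction("R1", {"A": 1.0}, lc.mass_action(1.0)),
    lc.Reaction("R2", {"A": -1.0, "B": 1.0, "E": -1.0},
                lc.mass_action(0.5, {"A": 1, "E": 1})),
    lc.Reaction("R3", {"B": -1.0, "E": -1.0},
                lc.mass_action(0.3, {"B": 1, "E": 1})),
    lc.Reaction("R4", {"E": 1.0}, lc.mass_action(0.8)),  # control: refill E
]
net = lc.ReactionNetwork(["A", "B", "E"], [0.5, 0.2, 1.0], rxns)
fs = lc.FunctionalitySet(
    net,
    [lc.Functionality("F1", {"R1", "R2"}), lc.Functionality("F2", {"R3"})],
    reserved={"R4"},
)
control = lc.ControlLayer(species=frozenset({"E"}), reactions=frozenset({"R4"}))

opts = lc.SolverOptions(n_grid=201)
cascade, ctrl = lc.simulate_with_control_layer(fs, control, None, 5.0, opts)
full = lc.simulate_full(net, 5.0, opts)
rec = lc.reconstruct_absolute(list(cascade) + [ctrl], net.x0)

print(f"cofactor pool E(end): full model {full.component('E')[-1]:.4f}, "
      f"control layer {net.x0[2] + ctrl.component('E')[-1]:.4f}")
print(f"reconstruction error vs direct simulation: "
      f"{np.nanmax(np.abs(rec - full.states)):.2e}")
for tr in cascade:
    print(f"cascade layer {tr.target[0]}: max |E-component| = "
          f"{np.nanmax(np.abs(tr.component('E'))):.1e} (control species stay out)")
print()
print("Reading: the control layer owns all cofactor dynamics while the")
print("cascaded layers read the shared pool; exactness of the sum shows the")
print("mixed structure loses nothing.")
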