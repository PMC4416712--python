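"""Two integral-feedback controllers on an unstable pathway.

The built-in perfect-adaptation fixture: a two-intermediate pathway (F1)
whose Y1-removing reactions saturate, plus two Michaelis-Menten integral
controllers (F2 observes Y1, F3 observes Y2).  After the production input
steps from k = 3 to k = 10 at t = 50, the pathway alone diverges at constant
slope while the assembled network adapts -- and the metrics quantify who
stabilises whom.
"""

import layercascade as lc
from layercascade.metrics import is_unstable

net, fs = lc.controller_model()
opts = lc.SolverOptions(n_grid=501)
horizon = 500.0

L1 = lc.simulate_isolated_layer(fs, "F1", horizon, opts)
full = lc.simulate_full(net, horizon, opts)
print(f"isolated pathway L(F1|F0): y1(end) = {L1.component('y1')[-1]:.0f}  "
      f"unstable: {is_unstable(L1)}")
print(f"assembled model:           y1(end) = {full.component('y1')[-1]:.3f}  "
      f"unstable: {is_unstable(full)}  (perfect adaptation)")

g = lc.populate_graph(lc.build_graph(fs), horizon, opts)
import numpy as np

for pair, label in [(("F1", "F2"), "pathway vs first controller"),
                    (("F1", "F3"), "pathway vs second controller"),
                    (("F2", "F3"), "the two controllers, no pathway")]:
    M = lc.mutual_dynamics(g, *pair)
    m_max = float(np.nanmax(np.abs(M.states)))
    if m_max < 1e-6:
        print(f"{label:34s}: no interaction (max |M| = {m_max:.1e})")
        continue
    I_end, C_end = lc.interaction_profile(g, *pair).end_values()
    print(f"{label:34s}: I -> {I_end:.3f}, C -> {C_end:+.3f}")
print()
print("Reading: I ~ 1 with C ~ -1 for (F1, F2) is the cancellation signature")
print("of a controller stabilising an unstable pathway; the second controller")
print("cannot observe Y1 and amplifies the instability slightly (C ~ +1 with")
print("small I); without the pathway the controllers share no species, their")
print("mutual dynamics vanish, and no interaction remains to classify.")
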