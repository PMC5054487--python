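"""Phase diagram of the optimal strategy over the permeability plane.

Sweeps a small (D_X, D_P) grid at two inhibition strengths and tabulates
the E_S asymmetry and the regime at each optimum. Asymmetric solutions
(A_S = 1) appear only under strong inhibition and only where the
intermediate diffuses faster than the product (D_X / D_P large).
"""

import numpy as np

import metcomp as mc

D_values = np.geomspace(0.05, 20.0, 5)
result = mc.phase_diagram(D_X_values=D_values, D_P_values=D_values,
                          inv_K_I_values=[0.1, 10.0],
                          options=mc.SolverOptions(n_starts=8, seed=2))
df = result.to_frame()
for inv_K_I, block in df.groupby("inv_K_I"):
    print(f"\n1/K_I = {inv_K_I}  (rows D_X, columns D_P; entries A_S)")
    table = block.pivot_table(index="D_X", columns="D_P", values="A_S")
    print(table.round(2).to_string())
    print("regimes:", sorted(block.regime.unique()))

# Under weak inhibition every entry is 0 (neutralist everywhere). Under
# strong inhibition the high-D_X / low-to-moderate-D_P corner flips to
# A_S = 1: cheater where the product cannot return, complementation where
# it can, and back to neutralist when D_P is so large that the product
# equilibrates and inhibition cannot be escaped.
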