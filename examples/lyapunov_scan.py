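"""Second-moment Lyapunov exponents across noise on the mean-field graph.

Scans sigma^2, extracting the moment exponent gamma_2 (slope of ln of the
node-averaged second moment), the sample exponent, the spectral radius of
the pair-space operator H2, and the analytic lower bound 2 sigma^2 - 2J<k>;
then locates the dynamical transition.
"""

import warnings

import numpy as np

import graphpam as gp

warnings.simplefilter("ignore")
J, n = 1.0, 50
g = gp.generate_mean_field(n)
grid = np.sort(1.0 / np.linspace(0.2, 3.0, 10))
table = gp.scan_phase_curve(g, J, grid, horizon=50.0)
print(table[["sigma_sq", "gamma2", "gamma2_hat", "lambda_max", "lower_bound"]].round(4))
det = gp.detect_transition(table, J, n)
print(f"\ngamma_2 sign change at J/sigma^2 = {det['J_over_sigma_sq']:.3f} (theory: 1)")
# Below the transition gamma_2 is pinned at the O(1/N) collective floor;
# above it the second moment grows at 2 sigma^2 - 2J, so noise beats mixing.
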