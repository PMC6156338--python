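"""Monte-Carlo SDE ensemble vs the exact moment ODE on a two-node graph.

Runs the Strang-split Stratonovich integrator, estimates second moments
with errors, and compares them with the matching pair-closure ODE; also
shows the Cole-Hopf height fields.
"""

import numpy as np

import graphpam as gp

g = gp.WeightedGraph(np.array([[0.0, 1.0], [1.0, 0.0]]))
cfg = gp.SimulationConfig(
    J=1.0, sigma=0.5, horizon=0.5, n_paths=20_000, seed=3, dt=0.005, store_every=100
)
ens = gp.simulate(g, cfg)
m2, se = gp.empirical_moment(ens, 2)
cross, cse = gp.empirical_pair_moment(ens, 0, 1)

op = gp.build_h2(g, 1.0, 0.25, include_cross_noise=True)  # Stratonovich closure
pv = gp.evolve_moments(op, np.ones(3), np.array([0.0, 0.5])).pair_values()[-1]
print(f"<m_1^2>(0.5):  MC {m2[-1, 0]:.4f} +- {se[-1, 0]:.4f}   ODE {pv[0]:.4f}")
print(f"<m_1 m_2>(0.5): MC {cross[-1]:.4f} +- {cse[-1]:.4f}   ODE {pv[1]:.4f}")

heights = gp.cole_hopf_heights(ens).heights
print(f"Cole-Hopf height spread at t=0.5: std = {heights[:, -1, :].std():.4f}")
# Agreement within ~2 standard errors validates both the integrator and the
# pair-space closure; the heights map the dynamics onto interface growth.
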