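# graphpam

Multiplicative-noise diffusion — the parabolic Anderson model — on general
weighted networks: exact spectral propagators, the all-orders
vertex-function (collision-matrix) resummation, second-moment dynamics with
graph Lyapunov exponents, a Stratonovich Monte-Carlo simulator, and the
closed-form mean-field phase structure.

## The model

On a weighted undirected graph with coupling matrix `W` and Laplacian
`L = diag(k) − W` (`k_i = Σ_j W_ij`), each node carries a positive field
`m_i(t)` — e.g. the magnetization of a pore in an MR measurement of a
porous medium such as brain tissue — evolving as (Stratonovich)

    dm_i/dt = −J Σ_j L_ij m_j + g_i(t) m_i ,
    ⟨g_i(t)⟩ = 0 ,  ⟨g_i(t) g_j(t′)⟩ = σ² δ_ij δ(t − t′).

Diffusion (strength `J`) spreads the field; multiplicative noise
(variance `σ²`) concentrates it. Which tendency wins depends on the
network topology through its **spectral dimension** `d̃`, defined by the
return-probability decay `P_ii(t) ~ t^{−d̃/2}` of the diffusion semigroup
`P(t) = Φ e^{−JΛt} Φᵀ`.

The two-point correlation function resums exactly into a geometric series
in the Laplace-domain **collision matrix** `Ĩ(s)` (the transform of
`P_ij(t)²`, two walkers meeting), giving the vertex function

    Γ̃(s) = (2σ²/N²) 1ᵀ (1 − σ² Ĩ(s))⁻¹ 1 ,

which diverges at a finite critical noise `σ_c² = 1/λ_max(Ĩ(s→0))` only on
transient (`d̃ > 2`) families — the critical spectral dimension is exactly
2. On the fully connected (mean-field) graph with per-pair weight `1/N`,
the normalized field `M_i = m_i/Σ m_j` has the stationary density
`P_eq(M) = A e^{−(μ−1)/M} / M^μ`, `A = (μ−1)^μ/Γ(μ)`, with Pareto exponent
`μ = 1 + 2J/σ²`; the stationary second moment `(μ−1)/(μ−3)` diverges at
`μ = 3`, i.e. `J/σ² = 1`. Growth rates are quantified by the graph moment
and sample Lyapunov exponents `γ₂` and `γ̂₂`, extracted from the exact
linear dynamics of all pair correlations `⟨m_r m_l⟩` (the pair-space
operator `H₂`), bounded by `γ̂₂ ≥ 2σ² − 2J⟨k⟩` and `γ₂ ≥ λ_max(H₂)`.

## Worked example

```python
import numpy as np, graphpam as gp

# spectral dimension of a ring vs a 3D periodic lattice
ring = gp.build_laplacian(gp.generate_torus(1, 400))
curve = gp.return_probability(ring, J=1.0, times=np.geomspace(1, 80, 40))
print(gp.estimate_spectral_dimension(curve, (5.0, 50.0)).d_tilde)
# 1.0090... — recurrent (d̃ ≤ 2): intermittent at any noise level

# critical noise on growing 3D tori from the collision-matrix resolvent
fam = gp.critical_sigma_family(
    [gp.torus_eigenvalues(3, n) for n in (8, 16, 32)], 1.0,
    2.0 ** -np.arange(13.0))
print(fam["verdict"], round(fam["sigma_c_sq"], 3))
# transient 8.63 — a finite-noise dynamical transition exists

# mean-field stationary second moment at mu = 5
print(gp.stationary_second_moment(gp.mu_param(1.0, 0.5)))
# 2.0 — finite fluctuations; diverges as sigma^2 -> J (mu -> 3)
```

The `examples/` directory holds one narrative script per capability
(`mean_field_phases.py`, `spectral_dimension.py`, `vertex_function.py`,
`lyapunov_scan.py`, `simulate_sde.py`); each builds a small input, runs the
method, and prints what the numbers mean. A thin CLI mirrors the library:

```bash
graphpam generate --kind torus --dimension 3 --side 6 --out torus.tsv
graphpam spectral torus.tsv --j 1.0 --sigma-sq 0.5 --out torus_spec.json
graphpam phase --j 1.0 --sigma-sq 0.5
```

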