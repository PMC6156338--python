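# Methods

## Model and assumptions

The package implements diffusion with multiplicative white noise on a
finite weighted graph: `dm_i/dt = −J Σ_j L_ij m_j + g_i m_i` with
`⟨g_i(t)g_j(t′)⟩ = σ² δ_ij δ(t−t′)`. Graphs are undirected, nonnegative,
without self loops, and fixed in time; the one directed exception is the
separable model `W_ij = b_j k_i` (Σb = 1), supported only by the simulator
and the pair-moment dynamics because the spectral machinery requires an
orthonormal Laplacian eigenbasis. Dense eigendecompositions cap graph sizes
at roughly N ≤ 2000; the pair-space dynamics go dense up to a pair
dimension of 2000 and sparse (matrix-exponential action, ARPACK on the N²
Kronecker form) beyond that.

## Noise conventions — a deliberate pair of closures

The literature around this model mixes two stochastic conventions, and the
package keeps both explicit rather than silently choosing one:

* **Stratonovich** (`convention="stratonovich"`, `include_cross_noise=True`):
  the SDE as written, solved substep-exactly by the geometric factor
  `exp(σ dW_i)`. Its exact pair closure is
  `d⟨m_r m_l⟩/dt = (1+δ_rl) σ² ⟨m_r m_l⟩ − J(L⊕L terms)`: independent
  geometric noises give distinct-site products the growth rate σ²
  (⟨m_r m_l⟩ = e^{σ²t} at J = 0).
* **Condensation** (`convention="condensation"`,
  `include_cross_noise=False`): the Itô dynamics with amplitude √2·σ,
  noise factor `exp(√2 σ dW − σ² dt)`. Its pair closure carries the noise
  term `2σ²` only on diagonal pairs — this is the closure behind the
  wealth-condensation mean-field results: the Pareto exponent
  `μ = 1 + 2J/σ²`, the stationary second moment `(μ−1)/(μ−3)` with its
  divergence at μ = 3 (`J/σ² = 1`), and the lower bound `2σ² − 2J⟨k⟩`
  with mean-field equality.

Both closures give `⟨m²⟩ = e^{2σ²t}` on an uncoupled node, so single-site
statistics cannot distinguish them; cross moments can, and the test suite
cross-validates each simulator convention against its own closure at
Monte-Carlo precision. The default `build_h2` closure is the condensation
one, which is the object the phase-structure results describe; Lyapunov and
phase scans use it throughout.

## Spectral machinery

All Laplace transforms are computed analytically in the eigenbasis
(numerical quadrature appears only as a test oracle). The collision matrix
`Ĩ_ij(s) = Σ_{αβ} φ_α^i φ_α^j φ_β^i φ_β^j / (s + J(λ_α + λ_β))` satisfies
the Hadamard row-sum identity `Σ_k Ĩ_ik(s) = ½ P̃_ii(s/2)` exactly; this is
the module's master invariant, tested to 1e-8 on every fixture. The
summability criterion is implemented as `Σ_α σ²/(s + 2Jλ_α)` — with a plus
sign in the denominator, consistent with the decaying propagator
`e^{−Jλt}`, although the source literature prints a minus.

The vertex function is implemented twice: the series
`Σ_l (2σ^{2l}/N²) 1ᵀ Ĩ^{l−1} 1` with its resolvent contraction
`(2σ²/N²) 1ᵀ(1−σ²Ĩ)⁻¹1`, and the trace form `(2σ²/N) Tr (1−σ²Ĩ)⁻¹`. The
two contract the end-point sums differently; they coincide for N = 1
(`2σ²/(1−σ²/s)`), which fixes the constant, and both are reported rather
than reconciling the normalization by guesswork. Series truncation defaults
to l_max = 200 with a relative-increment stop of 1e-10; the converged flag
additionally requires `σ² λ_max(Ĩ(s)) < 1`.

Degenerate eigenvalues are accepted with any orthonormal basis: every
downstream formula is basis-covariant within an eigenspace (tested by
re-randomizing degenerate blocks).

## Critical noise and the transient/recurrent dichotomy

On any finite connected graph `P_ii(t) → 1/N`, so `Ĩ(s)` has a stationary
rank-one part `(1/(N²s)) 11ᵀ` that diverges as s → 0 and would make every
finite graph look recurrent. `critical_sigma` therefore removes that
stationary part before taking `σ_c²(s) = 1/λ_max(Ĩ(s))` (for N = 1 the
removal would leave nothing, so the raw `Ĩ = 1/s` is used, giving
`σ_c²(s) = s`). For vertex-transitive graphs the row sums of `Ĩ(s)` are
constant, and by Perron–Frobenius `λ_max = ½ P̃_ii(s/2)` exactly — the fast
eigenvalue-only path used for large lattices via the closed-form circulant
spectra (`torus_eigenvalues`).

The s → 0 limit uses a geometric grid `s = s₀ 2^{−k}` (defaults s₀ = 1,
k ≤ 12) truncated at `s ≥ 2Jλ₁`: below the spectral gap a finite graph
saturates and stops approximating its infinite family. Per graph, the
verdict is read from the log-log slope of σ_c²(s) over the smallest usable
s (slope > 0.1 ⇒ power-law decay to zero, recurrent). Per *family* of
growing graphs, `critical_sigma_family` additionally requires
`σ_c²(s_min)` to change by < 10% between consecutive sizes. The two
conditions together emulate the infinite-graph dichotomy: rings fail the
slope test (σ_c² ~ √s), the marginal 2D lattice decays only
logarithmically and fails the cross-size test, and 3D lattices pass both
with σ_c² ≈ 8.6–9.4 (in units of J) across sides 8–32.

The critical spectral dimension is computed from the small-s law
`Σ_k Ĩ_ik(s) ∝ s^{−1+d̃/2}`: a finite σ_c² in the s → 0 limit requires the
factor to decay, which a numerical sweep classifies per d̃; the threshold
is the marginal dimension d̃ = 2 (where the asymptotic coefficient
`B/(2−d̃)` also diverges, so `asymptotic_vertex` rejects d̃ = 2). The
prefactor B is fitted on the *node-averaged* row sum, with a constant
term: on transient families the row sum tends to a constant and the power
is its singular correction.

## Second-moment dynamics and exponents

`H₂` acts on the N(N+1)/2 unordered pairs (the symmetry `⟨m_r m_l⟩ =
⟨m_l m_r⟩` is folded in; an N ≤ 6 test cross-checks against the full N²
evolution). Trajectories are advanced by the exact sparse
matrix-exponential action with per-interval renormalization, tracking the
accumulated log-scale separately so growth regimes never overflow.

Exponents are least-squares slopes over the last 20% of the horizon —
`γ₂` from `ln` of the node-averaged diagonal, `γ̂₂` from the node average of
the per-node logs — with the horizon doubling (cap: 3 doublings from the
default 50/J) until the slope stabilizes; fit residuals and the
stabilization flag are always reported. The spectral radius of H₂ is
computed densely for small systems and via the symmetric N² Kronecker form
(whose Perron eigenvector lies in the symmetric sector) for large ones.

**Finite-size transition detection.** On a finite graph
`λ_max(H₂) ≥ 2σ²/N > 0` (Rayleigh quotient of the uniform pair vector), so
γ₂ never literally changes sign; the infinite-N mean field has
`γ₂ = max(0, 2σ² − 2J)`. `detect_transition` therefore locates the
transition as the zero intercept of a straight-line fit to the high-noise
branch (points with γ₂ ≥ 30% of the scan maximum, falling back to the two
highest-noise points on coarse grids), validated by requiring the
points below half the intercept to sit within 3× of the collective floor
`2σ²/N`. Strict sign changes, when present, take precedence. On the
N = 50 complete graph this yields J/σ² = 1.04 against the analytic 1.

**Regime counting.** Scan points are labelled `flat` (γ₂ within 3× of the
collective floor — the would-be zero phase), `condensed` (the bound
`2σ² − 2J⟨k⟩` is positive and within 2% of γ₂ — condensation-dominated
growth), or `growth`. Scanned over σ² ∈ [J⟨k⟩/6, 4J⟨k⟩] (the condensation
scale J⟨k⟩ makes the window topology-independent), a 6³ lattice shows
flat → growth → condensed (two regime changes) while a ring is `growth`
throughout (none, matching the absence of a transition for d̃ ≤ 2). The
classifier constants absorb finite-size and finite-noise corrections
calibrated on the fixture topologies, where the separations are an order
of magnitude (floor ratios O(1) vs O(10); saturation residuals ~1% vs
~4%); the high-noise boundary is a descriptive regime change of the
second-moment curve, not a certified phase transition — the exact linear
dynamics cannot distinguish a genuine high-noise transition from the
crossover into bound-saturated growth.

## Monte-Carlo simulator

Strang splitting with both substeps exact: half-step diffusion semigroup
`exp(−JL dt/2)` (dense, precomputed once) around the entrywise geometric
noise factor. Positivity is preserved by construction, σ = 0 conserves
mass exactly, and the Cole–Hopf heights `h = ln m` are always defined.
`dt` defaults to `min(0.01, 0.01/(Jλ_max(L)))` — an accuracy choice; the
splitting is unconditionally stable. Noise blocks come from one Philox
stream keyed by the config seed (one (nodes × paths) block per step), so a
fixed config reproduces bit-identical ensembles.

**Heavy-tail statistics.** At μ = 5 the normalized stationary field is
inverse-gamma with shape 3, so its square has tail index 3/2: the sample
second moment follows a skewed stable law, not a CLT, with fluctuation
scale ~(C/n_eff)^{1/3} ≈ 3% at 10³ paths — and within-ensemble error bars
(jackknife, batch means) collapse on ensembles that happen to contain no
tail event. `meanfield_moment_ratio` reports a batch-means error as a
diagnostic, and the stationary-moment test uses three times the stable-law
scale (±0.2 on the value 2) as its tolerance. The ratio itself is the
cross-correlation-normalized second moment `⟨m_i²⟩/⟨m_i m_j⟩` (i ≠ j),
which is the quantity whose stationary value is `(μ−1)/(μ−3)`; the raw
second moment of the printed P_eq density differs from it by a factor
`(μ−1)/(μ−2)` (scale conventions of M differ across sources), so the
scale-free ratio is the primary check and the density comparison
(Kolmogorov–Smirnov distance with a resampled null; no p-value is claimed
because pooled samples are weakly dependent) is secondary.

## Synthetic data and what the tests do and do not show

All inputs are generated programmatically: complete graphs (weight 1/N —
the convention under which the drift is `J(m̄ − m_i)` and the printed
critical ratio J/σ² = 1 holds), periodic lattices in d = 1..4, seeded
random regular graphs, and the separable model. The fixture suite (mean
field N = 50, ring N = 100, 4-regular N = 100, 6³ torus, separable N = 20)
spans recurrent, transient, and mean-field behaviour at sizes where exact
eigendecompositions are cheap; problem sizes in the tests and the
acceptance script (N up to 10³ dense, lattice spectra up to ~3×10⁴ via
closed forms) were chosen so the full suite runs on one CPU in minutes.
Passing tests demonstrate the mathematical structure — identities,
inequalities, phase boundaries, convergence — on these clean topologies;
they do not establish anything about real pore networks, whose weights are
disordered, possibly non-stationary, and observed only through aggregate
signals.

## Known limitations

* The high-noise critical point σ²_cH is outside the perturbative
  machinery (mean field: +∞; general graphs: reported as not computable).
* The trace and double-sum contractions of the closed-form vertex function
  differ for N > 1; both are exposed.
* Spatially or temporally correlated noise, time-varying or signed
  weights, multigraphs, and p > 2 moment operators are out of scope.
* Whether γ₂ equals λ_max(H₂) beyond regular/transitive graphs is left
  open; the package asserts only the one-sided bound plus numerical
  equality on the 4-regular fixture.
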