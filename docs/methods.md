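# Methods

## Model class and simulator

All dynamics are reversible diffusions

    dX = −½ a ∇U(X) dt + σ dW,    a = σσᵀ  constant SPD,

whose stationary density is ∝ e^{−U}. Two benchmark systems are built
in: the Ornstein–Uhlenbeck (OU) process dX = −X dt + √2 dW
(U = x²/2, stationary law N(0,1), generator rates σᵢ = i−1 with Hermite
eigenfunctions) and a 2D double-well system with
U = 4x₁⁴ − 8x₁² + x₁ + x₂²/2 and σ = [[2,0],[−1,3]], whose slow mode is
hopping across the x₁ barrier (rate σ₂ ≈ 0.32 on the default grid,
confirmed both by grid refinement and by the simulated well-indicator
autocorrelation).

Trajectories come from Euler–Maruyama with internal step
Δ/`sub_steps`. Defaults: observation interval Δ = 0.05 in all studies;
internal step 0.01 for OU (bias well below statistical error at the
study trajectory lengths) and 10⁻³ for the double-well (its drift is
stiff near the wells). The OU process is initialized from its exact
stationary normal; the double-well starts near the wells and discards a
50-time-unit burn-in (≈ 16 hopping times). Replicate ensembles advance
in lockstep as one vectorized array from a single seeded generator;
replicates are independent noise streams of that generator, and a given
(seed, parameter) combination is bit-reproducible.

What the generator does *not* emulate: non-constant diffusion,
underdamped dynamics, observation noise, and the high-dimensional
feature spaces of real molecular data. Passing tests therefore
demonstrate correctness of the estimators and error formulas under
clean reversible sampling, not robustness to model misspecification.

## Grid oracle

The generator A f = ½ e^{U} ∇·(a e^{−U} ∇f) is discretized on a
tensor-product grid through its Dirichlet form: the stiffness matrix K
is assembled from face-centered two-point stencils for the axis terms
and cell-centered averaged gradients for the mixed a₁₂ term, with
e^{−U} face/cell weights, and L = −½ M̃⁻¹K. This makes detailed balance
*exact* in floating point (M L symmetric, L1 = 0, μᵀL = 0) — the
property every spectral statement downstream relies on — at second-order
accuracy. Boundaries are reflecting, which preserves the discrete
stationary weights exactly; `discretize` refuses domains whose boundary
density exceeds 10⁻¹² of the maximum. Default domains: [−7.5, 7.5] with
750 nodes (OU), [−2, 2] × [−7.5, 7.5] with 170 × 118 nodes
(double-well); both chosen so the truncated stationary mass is
negligible at that tolerance and verified by eigenvalue
self-convergence under refinement (≪ 1 %).

Rates and μ-orthonormal eigenfunctions come from the symmetrized
operator M^{1/2}(−L)M^{−1/2} (dense for 1D, shift-invert Lanczos in
2D). Exact correlation matrices use the spectral sum
C(τ)ᵢⱼ = Σ_l e^{−σ_l τ}⟨η_l, φᵢ⟩⟨η_l, φⱼ⟩ with C(0) the untruncated
Gram matrix; the truncation error is controlled by the completeness
defect dᵢ = C(0)ᵢᵢ − Σ_l⟨η_l, φᵢ⟩², since by Cauchy–Schwarz the omitted
tail is at most e^{−σ_r τ}√(dᵢdⱼ). In 1D the full grid spectrum is kept,
making the sum exact for the grid operator; in 2D, 200 modes hold the
tail below 10⁻⁶ of the diagonal scale for every lag on the study grid.

## Bases

Indicator partitions (Markov-state-model style) and monomial features.
Indicator cells are half-open with the rightmost cell closed;
out-of-range points evaluate to all-zero rows rather than raising, so
rare excursions do not abort long runs. Optional mean removal subtracts
stored means from every function, after which the constant eigenfunction
is intentionally absent from VAC output and subspace indices shift down
by one; it is off by default in all studies.

Two stock 1D layouts exist: `uniform_indicator_basis` (equal-width
cells, default span [−3, 3], optionally with outer edges extended) and
`gaussian_quantile_indicator_basis` (equal-probability cells under the
standard normal, outer edges clipped at ±7.5). The OU benchmark studies
use the quantile layout. The reason is statistical: equal-width cells
spanning a few standard deviations leave outer cells with a handful of
visits, and those starved indicators inflate the short-lag estimation
error of the fitted subspace far beyond what the study narratives
exhibit; equal-occupancy cells give every basis function the same
sampling weight — the indicator analogue of the density-adapted
partitions practitioners build by clustering data — at the price of a
larger approximation-error floor from wide tail cells.

## VAC estimator

Empirical correlations use the symmetrized time average over all frame
pairs at the given lag, normalized by the number of pairs (eigenvalues
and all diagnostics are invariant to the overall normalization; the
sampling interval reappears explicitly in the variance formulas).
Multiple trajectories pool their pair sums before normalizing. The
generalized problem is solved by whitening: directions of Ĉ(0) with
relative eigenvalue below 10⁻¹⁰ are dropped (this removes never-visited
indicator cells automatically), the whitened matrix is exactly
symmetric, so the returned eigenvalues are real and the coefficient
columns satisfy VᵀĈ(0)V = I. Signs are fixed by making each column's
largest-magnitude entry positive; ties in the descending eigenvalue sort
keep the whitened solver's order. Implied timescales −τ/log λ map
λ ≥ 1 to +∞ and λ ≤ 0 to NaN.

## Subspace distances

Subspaces carry either node values with stationary weights or basis
coefficients with a Gram metric; the two representations give identical
distances. d_F and d₂ are computed from the principal-angle *sines* —
singular values of the metric-weighted residual of one orthonormalized
basis after projection onto the other — because the textbook
cosine-based formula √(k − Σcos²) loses half the working precision to
cancellation exactly in the regime the theory cares about (nearly
coincident subspaces). When dim U > dim W the value is the distance to
the nearest dim U-dimensional superspace of W (at least
√(dim U − dim W), and d₂ = 1). Rank-deficient inputs raise rather than
silently reducing the dimension.

## Approximation-error bounds

The orthogonalized projections qᵢ are built by the exact Gram–Schmidt
recursion on P_Φηᵢ, with an informative failure when the projections are
linearly dependent. The classical subspace bound needs the operator norm
of P_{Φ⊥}T_τP_Φ, evaluated through the reference spectrum with the
spectral tail added as a safety margin (e^{−σ_r τ} times the root summed
completeness defect). The sharp long-lag bound multiplier
1 + ¼(e^{−σ_{k+1}τ}/(λ_kᵗ − e^{−σ_{k+1}τ}))² carries an applicability
flag (λ_kᵗ > e^{−σ_{k+1}τ}). For the exponential-convergence limit of
the eigenfunction subspaces we implement the quotient form
|⟨η_{k+1}, q_k⟩ / ⟨η_{k+1}, q_{k+1}⟩|, which is what the asymptotic
derivation produces. Two numerical facts worth knowing when exercising
these bounds: for *symmetric* bases the overlap ⟨η₃, q₂⟩ vanishes by
parity, degenerating that limit to zero (the distance then decays at
the next spectral gap), and the classical multiplier only diverges with
τ for indices where the spectral gap in its denominator closes faster
than the off-block norm decays (k ≥ 3 for the OU studies).

## Estimation-error diagnostics

The loss matrix L̂ᵢⱼ = vᵢᵀ[Ĉ(τ) − λⱼĈ(0)]vⱼ vanishes identically on the
pair used for fitting and gives first-order eigenvalue (diagonal) and
subspace (off-diagonal, gap-weighted) errors otherwise — verified by
Richardson extrapolation to have O(ε²) remainders. The condition number
uses the conventions λ₀ = +∞, λ_{m+1} = −∞; values above 5 are flagged
as prone to large estimation error.

The asymptotic mean squared error replaces the idealized γ, λ in the
loss time series F_lm(X_s, X_{s+τ}) by their plug-in estimates
(first-order consistent) and estimates each long-run variance
E|Z_lm|² = Δ·Σ_s autocov with a Bartlett taper. The taper is evaluated
through the moving-window-sum identity (sum of squared W-frame moving
sums over W·#windows), a single O(N) pass per pair, compiled with
numba; it equals the tapered autocovariance sum up to edge terms and is
cross-checked against the plain estimator in the tests. Default window:
min(⌊N/10⌋, ⌈5 t_slow/Δ⌉) frames with t_slow the slowest finite implied
timescale — the standard bias–variance compromise for
spectral-density-at-zero estimation, exposed as a parameter. Pairs whose
estimated eigenvalue gap is below 10⁻¹² are excluded from the subspace
sum and reported as unstable rather than producing infinities. The
calibration of the plug-in against brute-force replicate ensembles
(a 3-state reversible chain, and the OU studies) is part of the test
suite; at very short trajectory lengths the plug-in is compressed
because estimated eigenvalue gaps are biased outward, so the 1/T scaling
is asserted in the asymptotic regime.

## Benchmark studies

OU trials estimate span{η₁, η₂, η₃} over the lag grid
{0.05, 0.10, …, 1.5} with 30 replicates: trial 1 uses 20 cells and
T = 10⁴ (approximation-dominated; total error is minimized at a
comparatively long lag, ≈ 0.65 on this configuration, and the plug-in
error stays near or below 0.2 over the whole grid), trial 2 uses 50
cells and T = 500 (estimation-dominated; short optimal lag ≈ 0.1–0.2
and the plug-in error crosses 0.2 near τ ≈ 0.45). The double-well study
(T = 500, quadratic monomials {1, x₁, x₂, x₁², x₁x₂, x₂²}) contrasts
the pair subspace span{η₁, η₂} (min condition number ≈ 1.4 over this
grid, ≈ 2.0 near the error-optimal lag 0.2) with the triple
span{η₁, η₂, η₃} (condition number ≥ 15 everywhere, and strongly
lag-sensitive estimation error). "Optimal lag" always means the arg-min
of the RMS-over-replicates total-error curve; on flat valleys that
arg-min moves by a grid step or two between seeds, which is a property
of the statistic, not of the seed handling. Total and estimation errors
are measured in L²(μ) on the oracle grid by evaluating the fitted basis
coefficients on the nodes.

## Known limitations

* The oracle exists only for models with a known potential on a
  box; there is no unbounded-domain or adaptive discretization.
* Exact correlations require the reference rank to capture the basis
  (checked via the completeness defect); wildly oscillatory bases would
  need more modes.
* The plug-in MSE is a first-order asymptotic statement; it
  underestimates at small T and says nothing about the distribution
  tails.
* Only single stationary trajectories (optionally pooled) are
  supported — no reweighting of biased or enhanced-sampling data.
* Condition numbers and MSE refer to the retained (post-whitening)
  spectrum; with mean removal, indices refer to the nontrivial
  spectrum.
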