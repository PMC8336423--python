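# vacdyn

Spectral estimation of reversible Markov dynamics from trajectory data,
with a full error-analysis toolkit.

Slowly decorrelating functions of a stochastic system — conformational
coordinates of a biomolecule, large-scale modes of a diffusion — are the
leading eigenfunctions η₁, η₂, … of the Markov transition operator
T_τ f(x) = E[f(X_τ) | X₀ = x], with eigenvalues e^{−σᵢτ} set by the
relaxation rates σᵢ. The *variational approach to conformational
dynamics* (VAC, the mathematical core of Markov state models and of
time-lagged independent component analysis) estimates them from a
stationary trajectory and a basis (φᵢ)₁≤ᵢ≤ₙ by solving the generalized
eigenproblem

    Ĉ(τ) v = λ̂ Ĉ(0) v,        Ĉᵢⱼ(t) ≈ E_μ[φᵢ(X₀) φⱼ(X_t)],

returning eigenvalues λ̂ᵢ ≈ e^{−σᵢτ} and eigenfunctions
γ̂ᵢ = Σⱼ vⱼᵢ φⱼ ≈ ηᵢ. How good these estimates are depends on two very
different error sources, and `vacdyn` computes both:

* **approximation error** — the basis cannot represent the ηᵢ exactly.
  Evaluated exactly on benchmark diffusions through a grid oracle, with
  Rayleigh–Ritz bounds, an asymptotically sharp long-lag bound, and the
  τ→∞ limits (the orthogonalized projections qᵢ of the eigenfunctions
  onto the basis span).
* **estimation error** — finite data makes Ĉ noisy. Quantified by the
  *VAC condition number* κ = 1/min{λ_{j−1}−λ_j, λ_k−λ_{k+1}} of a
  subspace span{γ_j..γ_k}, and by a data-driven asymptotic mean squared
  error built from long-run variances of the loss time series
  F_lm(X_s, X_{s+τ}) — both computable from a single trajectory.

Distances between function subspaces are measured in L²(μ) by the
projection distance d_F (root-sum-of-squared principal-angle sines) and
the gap distance d₂ (largest sine).

The package ships its own data sources: an Euler–Maruyama simulator for
reversible diffusions dX = −½σσᵀ∇U dt + σ dW (a 1D Ornstein–Uhlenbeck
process and a 2D double-well system are built in) and a
detailed-balance-exact finite-difference discretization of the generator
that supplies true rates, eigenfunctions, stationary weights, and exact
correlation matrices for any basis.

## Worked example

Estimate the three slowest modes of the OU process dX = −X dt + √2 dW
from a single trajectory, using 20 equal-probability indicator cells
(a 1D Markov state model):

```python
import numpy as np
from vacdyn import (make_ou1d, simulate, solve_vac,
                    empirical_correlations, implied_timescales)
from vacdyn.basis import gaussian_quantile_indicator_basis
from vacdyn.diagnostics import asymptotic_mse, condition_number

traj = simulate(make_ou1d(), total_time=1e4, delta=0.05, sub_steps=5, seed=42)
basis = gaussian_quantile_indicator_basis(20)
sol = solve_vac(empirical_correlations(traj, basis, tau=0.5))
print("eigenvalues :", np.round(sol.eigenvalues[:4], 4))
print("timescales  :", np.round(implied_timescales(sol)[:4], 3))
print("kappa(1..3) :", round(condition_number(sol.eigenvalues, 1, 3), 3))
report = asymptotic_mse(traj, basis, sol, j=1, k=3)
print("root-MSE    :", round(report.root_mse, 4))
```

Output:

```
eigenvalues : [1.     0.5964 0.3254 0.1363]
timescales  : [  inf 0.967 0.445 0.251]
kappa(1..3) : 5.288
root-MSE    : 0.0395
```

The true OU rates are σᵢ = i−1, so at τ = 0.5 the exact eigenvalues are
(1, 0.6065, 0.3679, 0.2231) and the implied timescales should be
(∞, 1, 1/2, 1/3): the first two modes are estimated well, the slight
shortfall in λ̂₃, λ̂₄ is approximation error from the 20-cell basis. The
plug-in root mean squared estimation error 0.04 for span{γ̂₁,γ̂₂,γ̂₃}
says the T = 10⁴ trajectory is ample at this lag — the subspace is
statistically reliable even though its condition number (≈5) flags it as
moderately sensitive.

The same workflow is scripted for the built-in benchmark studies
(`vacdyn.experiments`): two OU trials contrasting basis size against
trajectory length (n = 20/T = 10⁴ vs n = 50/T = 500), and a 2D
double-well study contrasting a well-conditioned pair subspace with an
ill-conditioned triple. Each produces per-lag curves of the true
total/approximation/estimation errors (against the grid oracle) and the
data-driven error estimate.

A `vac` command-line tool wraps the library:

```bash
vac fit --traj ou.npz --basis basis.json --tau 0.5 --out results.json
vac bounds --model ou1d --basis basis.json --tau-grid "0.1 0.5 1.0" --k 2 --out bounds.csv
vac diagnose --traj ou.npz --basis basis.json --tau-grid "0.1 0.3 0.5" --subspace 1:3 --out diag.csv
vac experiment --name ou-trial1 --out results/
```

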