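"""Approximation-error bounds for idealized VAC, evaluated on grid oracles.

Idealized VAC (exact correlation matrices) is the Rayleigh--Ritz method
for the transition operator T_tau restricted to the basis span Phi.  This
module evaluates, on a :class:`~vacdyn.oracle.SpectralReference`:

* the orthogonalized projections q_1, ..., q_p -- Gram--Schmidt applied
  to the projected eigenfunctions P_Phi eta_i -- which are the tau -> inf
  limits of the idealized VAC eigenfunctions;
* the classical Rayleigh--Ritz eigenvalue bound
  1 - d_2^2(span eta_1..k, Phi) <= lambda_k^tau e^{sigma_k tau} <= 1;
* the classical subspace bound, whose multiplier
  1 + ||P_{Phi_perp} T_tau P_Phi||_2^2 / |e^{-sigma_k tau} - lambda_{k+1}^tau|^2
  diverges as tau grows because the denominator gap closes exponentially;
* the sharp long-lag subspace bound with multiplier
  1 + (1/4) (e^{-sigma_{k+1} tau} / (lambda_k^tau - e^{-sigma_{k+1} tau}))^2,
  valid when lambda_k^tau > e^{-sigma_{k+1} tau}, which tends to 1;
* the tau -> inf limits lambda_k^tau e^{sigma_k tau} -> <eta_k, q_k>^2 and
  d_F(Gamma_1..k, Q_1..k) lambda_k^tau / lambda_{k+1}^tau ->
  |<eta_{k+1}, q_k> / <eta_{k+1}, q_{k+1}>|  (the quotient form follows
  the asymptotic derivation of the exponential-convergence rate);
* the lag-time-independent bound
  d_F^2(span q_j..k, span eta_j..k)
  <= d_F^2(span eta_1..j-1, Phi) + d_F^2(span eta_1..k, Phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet, evaluate
from .core import solve_vac
from .oracle import SpectralReference, exact_correlations
from .subspaces import FunctionSubspace, orthonormalize, projection_distance, gap_distance

__all__ = [
    "QSet",
    "BoundReport",
    "orthogonalized_projections",
    "idealized_vac",
    "rayleigh_ritz_eigenvalue_bound",
    "rayleigh_ritz_subspace_bound",
    "sharp_subspace_bound",
    "long_lag_limits",
    "lag_independent_bound",
]


def _basis_on_grid(ref: SpectralReference, basis) -> np.ndarray:
    if isinstance(basis, BasisSet):
        return evaluate(basis, ref.domain.nodes())
    B = np.asarray(basis, dtype=float)
    if B.shape[0] != len(ref.mu):
        raise ValueError("basis values must be given on the oracle nodes")
    return B


def _subspace(ref: SpectralReference, cols: np.ndarray) -> FunctionSubspace:
    return FunctionSubspace(columns=cols, metric=ref.mu)


@dataclass(frozen=True)
class QSet:
    """Orthogonalized projections q_i of the true eigenfunctions onto Phi."""

    q: np.ndarray  # (n_nodes, p), mu-orthonormal, inside Phi
    overlaps: np.ndarray  # <eta_i, q_j> for i <= min(p+1, r), j <= p
    p: int


class ProjectionDependenceError(ValueError):
    """The projections P_Phi eta_i are linearly dependent, so the
    orthogonalized-projection recursion is undefined."""


def orthogonalized_projections(
    ref: SpectralReference, basis, p: int | None = None, tol: float = 1e-10
) -> QSet:
    """Gram--Schmidt on the projected eigenfunctions P_Phi eta_i.

    The recursion is q~_i = P_Phi eta_i - sum_{l<i} <q_l, eta_i> q_l,
    q_i = q~_i / ||q~_i||, run for i <= p = min(n, r).
    """
    B = _basis_on_grid(ref, basis)
    n = B.shape[1]
    if p is None:
        p = min(n, ref.r)
    if p > min(n, ref.r):
        raise ValueError("p cannot exceed min(n_basis, r)")
    Bo = orthonormalize(_subspace(ref, B)).columns  # mu-orthonormal basis of Phi
    mu = ref.mu

    def project(f):
        return Bo @ (Bo.T @ (mu * f))

    qs = []
    for i in range(p):
        eta = ref.eigenfunctions[:, i]
        qt = project(eta)
        for ql in qs:
            qt = qt - (ql @ (mu * eta)) * ql
        norm = np.sqrt(qt @ (mu * qt))
        if norm <= tol:
            raise ProjectionDependenceError(
                f"P_Phi eta_{i + 1} is linearly dependent on earlier "
                "projections; the orthogonalized projections require "
                "linear independence"
            )
        qs.append(qt / norm)
    Q = np.stack(qs, axis=-1)
    n_eta = min(p + 1, ref.r)
    overlaps = ref.eigenfunctions[:, :n_eta].T @ (mu[:, None] * Q)
    return QSet(q=Q, overlaps=overlaps, p=p)


@dataclass(frozen=True)
class BoundReport:
    """One evaluated bound: lower <= observed <= upper when applicable."""

    tau: float
    k: int
    lower: float
    upper: float
    observed: float
    applicable: bool = True
    kind: str = ""
    extras: dict = field(default_factory=dict)


def idealized_vac(ref: SpectralReference, basis, tau: float):
    """Idealized VAC at lag tau: (solution, eigenfunction grid values)."""
    B = _basis_on_grid(ref, basis)
    corr = exact_correlations(ref, B, tau)
    sol = solve_vac(corr)
    return sol, B @ sol.V


def rayleigh_ritz_eigenvalue_bound(
    ref: SpectralReference, basis, tau: float, k: int
) -> BoundReport:
    """Eigenvalue ratio bound: 1 - d_2^2(H_1..k, Phi) <= lambda_k e^{s_k tau} <= 1."""
    B = _basis_on_grid(ref, basis)
    if not 1 <= k <= ref.r:
        raise ValueError("k out of range")
    H = _subspace(ref, ref.eigenfunctions[:, :k])
    Phi = _subspace(ref, B)
    d2 = gap_distance(H, Phi)
    sol, _ = idealized_vac(ref, B, tau)
    observed = sol.eigenvalues[k - 1] / np.exp(-ref.rates[k - 1] * tau)
    return BoundReport(
        tau=tau, k=k, lower=1.0 - d2**2, upper=1.0, observed=float(observed),
        kind="rayleigh_ritz_eigenvalue", extras={"d2": d2},
    )


def offdiagonal_operator_norm(ref: SpectralReference, basis, tau: float) -> float:
    """|| P_{Phi_perp} T_tau P_Phi ||_2 on the oracle grid.

    Evaluated through the reference spectrum; the neglected spectral tail
    contributes at most e^{-sigma_r tau} sqrt(sum of completeness
    defects), which is added as a safety margin.
    """
    B = _basis_on_grid(ref, basis)
    Bo = orthonormalize(_subspace(ref, B)).columns
    mu = ref.mu
    ov = ref.eigenfunctions.T @ (mu[:, None] * Bo)  # (r, n)
    lam = np.exp(-ref.rates * tau)
    Y = ref.eigenfunctions @ (lam[:, None] * ov)  # T_tau acting on Bo
    Z = Y - Bo @ (Bo.T @ (mu[:, None] * Y))
    G = Z.T @ (mu[:, None] * Z)
    norm = float(np.sqrt(max(np.linalg.eigvalsh(G)[-1], 0.0)))
    defects = np.clip(1.0 - np.sum(ov**2, axis=0), 0.0, None)
    margin = np.exp(-ref.rates[-1] * tau) * np.sqrt(defects.sum())
    return norm + float(margin)


def _observed_subspace_ratio(ref, B, Gamma, k):
    """d_F^2(Gamma_1..k, H_1..k) / d_F^2(H_1..k, Phi); 1 on the 0/0 path
    (both distances at roundoff level, i.e. the basis contains the
    eigenfunctions)."""
    H = _subspace(ref, ref.eigenfunctions[:, :k])
    Phi = _subspace(ref, B)
    num = projection_distance(_subspace(ref, Gamma[:, :k]), H) ** 2
    den = projection_distance(H, Phi) ** 2
    if den < 1e-12:
        return (1.0 if num < 1e-12 else np.inf), num, den
    return num / den, num, den


def rayleigh_ritz_subspace_bound(
    ref: SpectralReference, basis, tau: float, k: int
) -> BoundReport:
    """Classical subspace bound; diverges as tau grows (gap in the
    denominator closes exponentially) even though the observed ratio
    stays bounded."""
    B = _basis_on_grid(ref, basis)
    sol, Gamma = idealized_vac(ref, B, tau)
    if sol.m < k + 1:
        raise ValueError("need at least k+1 idealized eigenvalues")
    ratio, num, den = _observed_subspace_ratio(ref, B, Gamma, k)
    gap = np.exp(-ref.rates[k - 1] * tau) - sol.eigenvalues[k]
    applicable = abs(gap) > 1e-14
    opnorm = offdiagonal_operator_norm(ref, B, tau)
    upper = 1.0 + (opnorm**2 / gap**2 if applicable else np.inf)
    return BoundReport(
        tau=tau, k=k, lower=1.0, upper=float(upper), observed=float(ratio),
        applicable=bool(applicable), kind="rayleigh_ritz_subspace",
        extras={"opnorm": opnorm, "gap": float(gap), "num": num, "den": den},
    )


def sharp_subspace_bound(
    ref: SpectralReference, basis, tau: float, k: int
) -> BoundReport:
    """Sharp long-lag bound: multiplier
    1 + (1/4)(e^{-sigma_{k+1} tau} / (lambda_k - e^{-sigma_{k+1} tau}))^2,
    applicable when lambda_k^tau > e^{-sigma_{k+1} tau}."""
    B = _basis_on_grid(ref, basis)
    sol, Gamma = idealized_vac(ref, B, tau)
    if k + 1 > ref.r:
        raise ValueError("need sigma_{k+1} in the reference spectrum")
    lam_k = sol.eigenvalues[k - 1]
    mu_next = np.exp(-ref.rates[k] * tau)
    applicable = lam_k > mu_next
    ratio, num, den = _observed_subspace_ratio(ref, B, Gamma, k)
    upper = (
        1.0 + 0.25 * (mu_next / (lam_k - mu_next)) ** 2 if applicable else np.inf
    )
    return BoundReport(
        tau=tau, k=k, lower=1.0, upper=float(upper), observed=float(ratio),
        applicable=bool(applicable), kind="sharp_subspace",
        extras={"lambda_k": float(lam_k), "next_true": float(mu_next)},
    )


def long_lag_limits(
    ref: SpectralReference, basis, qset: QSet, tau_grid, k: int,
    gap_tol: float = 1e-8,
) -> dict:
    """Observed long-lag quantities against their predicted limits.

    For each tau: lambda_k^tau e^{sigma_k tau} (limit <eta_k, q_k>^2) and
    d_F(Gamma_1..k, Q_1..k) lambda_k^tau / lambda_{k+1}^tau
    (limit |<eta_{k+1}, q_k> / <eta_{k+1}, q_{k+1}>|).
    """
    B = _basis_on_grid(ref, basis)
    if k + 1 > qset.p:
        raise ValueError("need q_{k+1} in the QSet")
    gaps_ok = (
        (k == 1 or ref.rates[k - 1] - ref.rates[k - 2] > gap_tol)
        and ref.rates[k] - ref.rates[k - 1] > gap_tol
        and (k + 1 >= ref.r or ref.rates[k + 1] - ref.rates[k] > gap_tol)
    )
    Qk = _subspace(ref, qset.q[:, :k])
    rows = {"tau": [], "eig_ratio": [], "df_gamma_q": [], "df_scaled": []}
    for tau in np.asarray(tau_grid, dtype=float):
        sol, Gamma = idealized_vac(ref, B, tau)
        lam = sol.eigenvalues
        rows["tau"].append(tau)
        rows["eig_ratio"].append(
            float(lam[k - 1] * np.exp(ref.rates[k - 1] * tau))
        )
        df = projection_distance(_subspace(ref, Gamma[:, :k]), Qk)
        rows["df_gamma_q"].append(df)
        rows["df_scaled"].append(df * lam[k - 1] / lam[k])
    eig_limit = float(qset.overlaps[k - 1, k - 1] ** 2)
    df_limit = float(
        abs(qset.overlaps[k, k - 1] / qset.overlaps[k, k])
    )
    return {
        "table": {key: np.asarray(val) for key, val in rows.items()},
        "eig_limit": eig_limit,
        "df_limit": df_limit,
        "gaps_ok": bool(gaps_ok),
        "k": k,
    }


def lag_independent_bound(ref: SpectralReference, basis, j: int, k: int) -> dict:
    """Both sides of
    d_F^2(span q_j..k, span eta_j..k)
       <= d_F^2(span eta_1..j-1, Phi) + d_F^2(span eta_1..k, Phi)."""
    if not 1 <= j <= k:
        raise ValueError("need 1 <= j <= k")
    B = _basis_on_grid(ref, basis)
    qset = orthogonalized_projections(ref, B, p=k)
    Phi = _subspace(ref, B)
    left = projection_distance(
        _subspace(ref, qset.q[:, j - 1 : k]),
        _subspace(ref, ref.eigenfunctions[:, j - 1 : k]),
    ) ** 2
    right = projection_distance(
        _subspace(ref, ref.eigenfunctions[:, :k]), Phi
    ) ** 2
    if j > 1:
        right += projection_distance(
            _subspace(ref, ref.eigenfunctions[:, : j - 1]), Phi
        ) ** 2
    return {"left": float(left), "right": float(right), "holds": left <= right + 1e-10}
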