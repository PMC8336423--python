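"""Estimation-error diagnostics computable from trajectory data.

Three tools quantify how sensitive VAC output is to statistical noise in
the correlation matrices:

* the loss matrix L_ij(tau) = v_i^T [C_hat(tau) - lambda_j C_hat(0)] v_j,
  whose entries give the first-order eigenvalue error (diagonal) and,
  divided by eigenvalue gaps, the first-order subspace error;
* the VAC condition number kappa = 1 / min(lambda_{j-1} - lambda_j,
  lambda_k - lambda_{k+1}) of a subspace spanned by eigenfunctions
  j..k -- the amplification factor from correlation-matrix error to
  subspace error (conventions lambda_0 = +inf, lambda_{n+1} = -inf);
* the asymptotic mean squared estimation error, obtained by a
  central-limit argument: sqrt(T) (lambda_hat - lambda) and the scaled
  subspace error are asymptotically Gaussian with long-run variances
  E|Z_lm|^2 = Delta * sum_s Cov[F_lm(X_0, X_tau), F_lm(X_s, X_{s+tau})],
  where F_lm(x, y) = (gamma_l(x)gamma_m(y) + gamma_l(y)gamma_m(x))/2
  - lambda_m (gamma_l(x)gamma_m(x) + gamma_l(y)gamma_m(y))/2.
  The doubly infinite covariance sum is estimated with a Bartlett taper,
  computed through the moving-window-sum identity (O(N) per pair), with
  the idealized gamma, lambda replaced by their plug-in estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .basis import BasisSet, evaluate
from .core import CorrelationPair, VacSolution, implied_timescales
from .models import Trajectory

__all__ = [
    "LossMatrix",
    "ConditionReport",
    "MseReport",
    "loss_matrix",
    "condition_number",
    "minimum_condition_number",
    "long_run_variance",
    "asymptotic_mse",
]

CONDITION_NUMBER_WARN = 5.0  # above this, large estimation error is likely
RMSE_WARN = 0.2  # root-MSE level where estimation error becomes material


@dataclass(frozen=True)
class LossMatrix:
    entries: np.ndarray  # (m, m)
    tau: float
    source: str = ""


def loss_matrix(corr_hat: CorrelationPair, sol: VacSolution) -> LossMatrix:
    """L_ij = v_i^T [C_hat(tau) - lambda_j C_hat(0)] v_j.

    Vanishes identically when `corr_hat` is the pair `sol` was fitted to;
    on an independently estimated pair its entries are the first-order
    eigenvalue and subspace errors.
    """
    V = sol.V
    if corr_hat.C0.shape[0] != V.shape[0]:
        raise ValueError("correlation size does not match solution")
    A = V.T @ corr_hat.Ct @ V
    B = V.T @ corr_hat.C0 @ V
    L = A - B * sol.eigenvalues[None, :]
    return LossMatrix(entries=L, tau=sol.tau, source=corr_hat.source)


def condition_number(eigenvalues, j: int, k: int) -> float:
    """kappa = 1 / min(lambda_{j-1} - lambda_j, lambda_k - lambda_{k+1}).

    `eigenvalues` are sorted descending; j, k are 1-based with
    lambda_0 = +inf and lambda_{m+1} = -inf.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    m = len(lam)
    if not 1 <= j <= k <= m:
        raise ValueError(f"need 1 <= j <= k <= {m}")
    upper_gap = np.inf if j == 1 else lam[j - 2] - lam[j - 1]
    lower_gap = np.inf if k == m else lam[k - 1] - lam[k]
    return 1.0 / min(upper_gap, lower_gap)


@dataclass(frozen=True)
class ConditionReport:
    j: int
    k: int
    taus: np.ndarray
    kappas: np.ndarray
    kappa_min: float
    ill_conditioned: bool  # kappa_min above the rule-of-thumb threshold
    source: str = ""


def minimum_condition_number(
    solutions: list[VacSolution], j: int, k: int
) -> ConditionReport:
    """Per-lag condition numbers and their minimum over the lag grid."""
    taus = np.array([s.tau for s in solutions])
    kappas = np.array([condition_number(s.eigenvalues, j, k) for s in solutions])
    kmin = float(np.min(kappas))
    return ConditionReport(
        j=j, k=k, taus=taus, kappas=kappas, kappa_min=kmin,
        ill_conditioned=kmin > CONDITION_NUMBER_WARN,
        source=solutions[0].source if solutions else "",
    )


def long_run_variance(series: np.ndarray, window: int) -> np.ndarray:
    """Bartlett-tapered long-run variance per row of `series` (rows, N).

    Computes sum_{|h| < window} (1 - |h|/window) * acov(h) through the
    moving-window-sum identity: with M_t the sum of `window` consecutive
    demeaned values, the estimator is sum_t M_t^2 / (window * #windows).
    Units: per-frame (multiply by the sampling interval for a time-unit
    long-run variance).
    """
    F = np.atleast_2d(np.asarray(series, dtype=float))
    N = F.shape[1]
    if not 1 <= window <= N:
        raise ValueError(f"window must be in [1, {N}]")
    F = F - F.mean(axis=1, keepdims=True)
    c = np.cumsum(F, axis=1)
    mov = c[:, window - 1 :].copy()
    mov[:, 1:] -= c[:, : N - window]
    return np.sum(mov**2, axis=1) / (window * mov.shape[1])


@njit(cache=False)
def _bartlett_pair_lrv(X0, X1, lam, ls, ms, W):
    """Bartlett long-run variance of F_lm(X_s, X_{s+lag}) per pair.

    Single fused pass: F is built on the fly and the tapered sum is
    evaluated through raw moving-window sums, mean-corrected at the end
    (sum_t (M_t - W mean)^2 = sum M^2 - 2 W mean sum M + n W^2 mean^2).
    Matches `long_run_variance` exactly (per-frame units).
    """
    n_pairs = ls.shape[0]
    N = X0.shape[0]
    out = np.empty(n_pairs)
    F = np.empty(N)
    nw = N - W + 1
    for p in range(n_pairs):
        l, m = ls[p], ms[p]
        lam_m = lam[m]
        mean = 0.0
        for s in range(N):
            v = 0.5 * (X0[s, l] * X1[s, m] + X1[s, l] * X0[s, m]) \
                - 0.5 * lam_m * (X0[s, l] * X0[s, m] + X1[s, l] * X1[s, m])
            F[s] = v
            mean += v
        mean /= N
        run = 0.0
        for s in range(W):
            run += F[s]
        acc = run * run
        total = run
        for t in range(1, nw):
            run += F[t + W - 1] - F[t - 1]
            acc += run * run
            total += run
        wm = W * mean
        acc += -2.0 * wm * total + nw * wm * wm
        out[p] = acc / (W * nw)
    return out


@dataclass(frozen=True)
class MseReport:
    """Plug-in asymptotic estimation error for a subspace j..k."""

    j: int
    k: int
    tau: float
    T: float
    window: int
    pair_variances: dict  # (l, m) -> E|Z_lm|^2, 1-based indices
    eigenvalue_variances: dict  # i -> E|Z_ii|^2
    subspace_mse: float  # sum E|Z_lm|^2 / (lambda_l - lambda_m)^2 / T
    root_mse: float
    eigenvalue_mse: dict  # i -> E|Z_ii|^2 / T
    unstable_pairs: tuple = ()  # pairs excluded for near-zero gaps


def asymptotic_mse(
    traj: Trajectory,
    basis: BasisSet,
    sol: VacSolution,
    j: int,
    k: int,
    window: int | None = None,
    gap_tol: float = 1e-12,
    basis_values: np.ndarray | None = None,
) -> MseReport:
    """Plug-in mean squared estimation error for span(gamma_j..gamma_k).

    Builds the time series F_lm(X_s, X_{s+tau}) from the estimated VAC
    eigenfunctions and eigenvalues, estimates each long-run variance
    E|Z_lm|^2 with a Bartlett taper, and assembles the asymptotic
    subspace MSE sum_{l notin j..k, m in j..k} E|Z_lm|^2/(lambda_l -
    lambda_m)^2 / T along with per-eigenvalue variances E|Z_ii|^2 / T.

    The default window is min(N//10, ceil(5 t_slow / Delta)) frames,
    where t_slow is the slowest finite implied timescale of `sol`.
    """
    m_rank = sol.m
    if not 1 <= j <= k <= m_rank:
        raise ValueError(f"need 1 <= j <= k <= {m_rank}")
    delta = traj.delta
    lag = int(round(sol.tau / delta))
    if abs(lag * delta - sol.tau) > 1e-9 * max(delta, 1.0):
        raise ValueError("solution lag time is not on the frame grid")

    if basis_values is None:
        basis_values = evaluate(basis, traj.states)
    G = basis_values @ sol.V  # gamma_hat values, (N, m)
    N = G.shape[0] - lag
    if N < 2:
        raise ValueError("trajectory too short for this lag")
    X0, X1 = G[:-lag] if lag else G, G[lag:] if lag else G

    if window is None:
        ts = implied_timescales(sol)
        finite = ts[np.isfinite(ts)]
        t_slow = float(finite.max()) if finite.size else np.inf
        window = int(min(N // 10, np.ceil(5.0 * t_slow / delta)))
        window = max(window, 1)

    if not 1 <= window <= N:
        raise ValueError(f"window must be in [1, {N}]")
    lam = sol.eigenvalues
    inside = np.arange(j - 1, k)
    outside = np.array([i for i in range(m_rank) if i < j - 1 or i > k - 1],
                       dtype=int)
    T_total = traj.total_time

    ls = np.concatenate([np.repeat(outside, len(inside)), inside])
    ms = np.concatenate([np.tile(inside, len(outside)), inside])
    lrvs = delta * _bartlett_pair_lrv(
        np.ascontiguousarray(X0), np.ascontiguousarray(X1), lam,
        ls.astype(np.int64), ms.astype(np.int64), window,
    )
    n_off = len(outside) * len(inside)
    pair_vars = {
        (int(l) + 1, int(m) + 1): float(v)
        for l, m, v in zip(ls[:n_off], ms[:n_off], lrvs[:n_off])
    }
    eig_vars = {int(i) + 1: float(v) for i, v in zip(inside, lrvs[n_off:])}

    mse = 0.0
    unstable = []
    for (l1, m1), var in pair_vars.items():
        gap = lam[l1 - 1] - lam[m1 - 1]
        if abs(gap) < gap_tol:
            unstable.append((l1, m1))
            continue
        mse += var / gap**2
    mse /= T_total

    return MseReport(
        j=j, k=k, tau=sol.tau, T=T_total, window=window,
        pair_variances=pair_vars, eigenvalue_variances=eig_vars,
        subspace_mse=float(mse), root_mse=float(np.sqrt(mse)),
        eigenvalue_mse={i: v / T_total for i, v in eig_vars.items()},
        unstable_pairs=tuple(unstable),
    )
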