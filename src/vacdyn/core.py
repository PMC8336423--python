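"""The VAC estimator: correlation matrices and the generalized eigenproblem.

Given basis functions (phi_i) and a lag time tau, VAC forms

    C_ij(0) = E_mu[ phi_i(X_0) phi_j(X_0) ],
    C_ij(tau) = E_mu[ phi_i(X_0) phi_j(X_tau) ],

and solves C(tau) v = lambda C(0) v.  The eigenvalues estimate the
transition-operator eigenvalues exp(-sigma_i tau) and the functions
gamma_i = sum_j v_ji phi_j estimate the eigenfunctions eta_i.  Empirical
("hatted") matrices use symmetrized time averages over a stationary
trajectory; idealized matrices come from the grid oracle.

The generalized problem is solved by whitening: directions of C(0) with
relative eigenvalue below `rank_tol` are dropped (this silently removes
e.g. indicator cells the trajectory never visited), the problem becomes
symmetric in the whitened coordinates, and the returned eigenvalues are
therefore exactly real with C(0)-orthonormal coefficient columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSet, evaluate
from .models import Trajectory

__all__ = [
    "CorrelationPair",
    "VacSolution",
    "empirical_correlations",
    "solve_vac",
    "eigenfunction_values",
    "implied_timescales",
]


@dataclass(frozen=True)
class CorrelationPair:
    C0: np.ndarray
    Ct: np.ndarray
    tau: float
    n_frames_used: int = 0
    source: str = "empirical"  # "empirical" | "oracle"

    def __post_init__(self):
        for name in ("C0", "Ct"):
            M = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, 0.5 * (M + M.T))

    @property
    def n(self) -> int:
        return self.C0.shape[0]


def _lagged_sum(Y: np.ndarray, lag: int) -> tuple[np.ndarray, int]:
    """Symmetrized sum over pairs (s, s+lag); returns (matrix, n_pairs)."""
    npairs = Y.shape[0] - lag
    if lag == 0:
        A = Y.T @ Y
        return A, npairs
    A = Y[:-lag].T @ Y[lag:]
    return 0.5 * (A + A.T), npairs


def empirical_correlations(
    traj: Trajectory | list[Trajectory], basis: BasisSet, tau: float
) -> CorrelationPair:
    """Symmetrized empirical C(0), C(tau) from one or more trajectories.

    Each entry averages [phi_i(X_s) phi_j(X_{s+tau}) + (i <-> j)]/2 over
    all frame pairs at lag tau; C(0) uses every frame.  With multiple
    trajectories the pair sums are pooled before normalization.  The
    overall normalization is 1/#pairs (VAC eigenvalues and all
    diagnostics are invariant to this convention; the sampling interval
    reappears explicitly in the variance formulas).
    """
    trajs = traj if isinstance(traj, (list, tuple)) else [traj]
    delta = trajs[0].delta
    lag = int(round(tau / delta))
    if abs(lag * delta - tau) > 1e-9 * max(delta, 1.0):
        raise ValueError(f"tau={tau} is not a multiple of delta={delta}")

    S0 = St = None
    n0 = nt = 0
    for tr in trajs:
        if abs(tr.delta - delta) > 1e-12:
            raise ValueError("pooled trajectories must share delta")
        if lag >= tr.n_frames:
            raise ValueError("tau must be shorter than the trajectory")
        Y = evaluate(basis, tr.states)
        A0, m0 = _lagged_sum(Y, 0)
        At, mt = _lagged_sum(Y, lag)
        S0 = A0 if S0 is None else S0 + A0
        St = At if St is None else St + At
        n0 += m0
        nt += mt
    if nt < 10:
        raise ValueError(f"only {nt} frame pairs at lag {lag}; need >= 10")
    return CorrelationPair(
        C0=S0 / n0, Ct=St / nt, tau=lag * delta, n_frames_used=n0,
        source="empirical",
    )


@dataclass(frozen=True)
class VacSolution:
    """Solution of C(tau) v = lambda C(0) v, eigenvalues descending.

    `V` has C(0)-orthonormal columns (V^T C0 V = I) spanning the retained
    rank; `gamma_i = sum_j V[j, i] phi_j` are the VAC eigenfunctions.
    """

    tau: float
    eigenvalues: np.ndarray  # (m,), descending
    V: np.ndarray  # (n, m)
    retained_rank: int
    dropped: int = 0
    source: str = "empirical"

    @property
    def m(self) -> int:
        return len(self.eigenvalues)


def solve_vac(corr: CorrelationPair, rank_tol: float = 1e-10) -> VacSolution:
    """Solve the symmetric-definite generalized eigenproblem by whitening."""
    C0, Ct = corr.C0, corr.Ct
    if not (np.all(np.isfinite(C0)) and np.all(np.isfinite(Ct))):
        raise ValueError("correlation matrices contain non-finite entries")
    s, E = np.linalg.eigh(C0)
    smax = s[-1]
    if smax <= 0:
        raise ValueError("C(0) is numerically zero")
    keep = s > rank_tol * smax
    dropped = int(np.sum(~keep))
    W = E[:, keep] / np.sqrt(s[keep])  # whitening: W^T C0 W = I
    lam, U = np.linalg.eigh(W.T @ Ct @ W)
    order = np.argsort(lam, kind="stable")[::-1]
    lam, U = lam[order], U[:, order]
    V = W @ U
    # deterministic sign: largest-|.| coefficient entry positive
    for i in range(V.shape[1]):
        jmax = np.argmax(np.abs(V[:, i]))
        if V[jmax, i] < 0:
            V[:, i] = -V[:, i]
    return VacSolution(
        tau=corr.tau, eigenvalues=lam, V=V, retained_rank=int(np.sum(keep)),
        dropped=dropped, source=corr.source,
    )


def eigenfunction_values(
    sol: VacSolution, basis: BasisSet, points: np.ndarray
) -> np.ndarray:
    """Values gamma_i(x) = sum_j V[j,i] phi_j(x) at `points`: (frames, m)."""
    Y = evaluate(basis, points)
    if Y.shape[1] != sol.V.shape[0]:
        raise ValueError("basis size does not match solution coefficients")
    return Y @ sol.V


def implied_timescales(sol: VacSolution) -> np.ndarray:
    """t_i = -tau / log(lambda_i); +inf for lambda >= 1, NaN for lambda <= 0."""
    if sol.tau <= 0:
        raise ValueError("implied timescales require tau > 0")
    lam = sol.eigenvalues
    out = np.full(lam.shape, np.nan)
    out[lam >= 1.0] = np.inf
    ok = (lam > 0.0) & (lam < 1.0)
    out[ok] = -sol.tau / np.log(lam[ok])
    return out
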