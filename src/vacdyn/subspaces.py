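"""Distances between function subspaces of L^2(mu).

A subspace is represented by a matrix of column vectors together with a
metric: either per-node stationary weights (grid representation) or a
Gram matrix (coefficients in a basis).  The two distances are

    d_2(U, W) = || P_{W_perp} P_U ||_2    (largest principal-angle sine),
    d_F(U, W) = || P_{W_perp} P_U ||_F    (root-sum-square of sines),

computed from the singular values (= principal-angle cosines) of the
cross-product of orthonormalized bases.  When dim(U) > dim(W) the values
measure the distance from U to the nearest dim(U)-dimensional subspace
containing W, in which case d_F >= sqrt(dim U - dim W) and a flag is set
on the returned report.

The total/approximation/estimation error decomposition of spectral
estimation lives here too: total (data vs truth) is bounded by
approximation (ideal vs truth) plus estimation (data vs ideal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "FunctionSubspace",
    "orthonormalize",
    "projection_distance",
    "gap_distance",
    "error_decomposition",
]


@dataclass(frozen=True)
class FunctionSubspace:
    """Columns spanning a subspace, with the inner-product metric.

    metric: 1-D array -> diagonal weights (grid values in L^2(mu_h));
            2-D array -> Gram/metric matrix for coordinate vectors.
    """

    columns: np.ndarray
    metric: np.ndarray

    def __post_init__(self):
        cols = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if cols.ndim == 1:
            cols = cols[:, None]
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "metric", np.asarray(self.metric, dtype=float))

    @property
    def k(self) -> int:
        return self.columns.shape[1]

    def _apply_metric(self, X: np.ndarray) -> np.ndarray:
        if self.metric.ndim == 1:
            return self.metric[:, None] * X
        return self.metric @ X

    def gram(self, other: "FunctionSubspace | None" = None) -> np.ndarray:
        other = self if other is None else other
        return self.columns.T @ self._apply_metric(other.columns)


class RankDeficiencyError(ValueError):
    """Subspace columns are linearly dependent under the metric."""


def orthonormalize(sub: FunctionSubspace, tol: float = 1e-10) -> FunctionSubspace:
    """Orthonormal columns spanning the same subspace (metric-aware).

    Raises :class:`RankDeficiencyError` if the Gram matrix is singular
    relative to `tol` -- degenerate inputs always error rather than
    silently reducing the dimension.
    """
    G = sub.gram()
    s, E = np.linalg.eigh(G)
    if s[0] <= tol * max(s[-1], 1e-300) or s[-1] <= 0:
        raise RankDeficiencyError(
            f"Gram matrix is rank deficient (eig ratio {s[0] / s[-1]:.2e})"
        )
    T = E / np.sqrt(s)
    return FunctionSubspace(columns=sub.columns @ T, metric=sub.metric)


def _principal_sines(U: FunctionSubspace, W: FunctionSubspace) -> np.ndarray:
    """Singular values of P_{W_perp} P_U (principal-angle sines).

    Computed from the metric-weighted residual of U's orthonormal basis
    after projection onto W, which is accurate for small angles (the
    cosine-based formula sqrt(dim U - sum cos^2) loses half the digits
    to cancellation when the subspaces nearly coincide).
    """
    if U.columns.shape[0] != W.columns.shape[0]:
        raise ValueError("subspaces live in different representation spaces")
    A = orthonormalize(U).columns
    B = orthonormalize(W).columns
    MA = U._apply_metric(A)
    R = A - B @ (B.T @ MA)  # (I - P_W) a_i
    if U.metric.ndim == 1:
        Rw = np.sqrt(U.metric)[:, None] * R
    else:
        Rw = np.linalg.cholesky(U.metric).T @ R
    s = scipy.linalg.svdvals(Rw)
    return np.clip(s, 0.0, 1.0)


def projection_distance(U: FunctionSubspace, W: FunctionSubspace) -> float:
    """d_F(U, W): root-sum-square of the principal-angle sines.

    For dim(U) > dim(W) this is the distance from U to the nearest
    dim(U)-dimensional subspace containing W, at least
    sqrt(dim U - dim W)."""
    s = _principal_sines(U, W)
    return float(np.sqrt(np.sum(s**2)))


def gap_distance(U: FunctionSubspace, W: FunctionSubspace) -> float:
    """d_2(U, W): the largest principal-angle sine (1 if dim U > dim W)."""
    s = _principal_sines(U, W)
    return float(s[0])


def error_decomposition(
    est: FunctionSubspace, ideal: FunctionSubspace, truth: FunctionSubspace
) -> dict:
    """Split the total subspace error into approximation + estimation.

    total = d_F(est, truth) <= d_F(ideal, truth) + d_F(est, ideal)
    (approximation error from the basis, estimation error from the data).
    """
    return {
        "total": projection_distance(est, truth),
        "approximation": projection_distance(ideal, truth),
        "estimation": projection_distance(est, ideal),
    }
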