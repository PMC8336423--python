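"""Basis sets for VAC: indicator partitions (MSM-style) and monomials.

A basis set is a finite family (phi_i) of functions of the state whose
span approximates the leading eigenfunctions of the transition operator.
Indicator functions on a partition of an axis recover classical Markov
state models; monomial features recover polynomial VAC.  Optionally the
(estimated) mean can be removed from every basis function, in which case
the trivial constant eigenfunction is no longer estimated and all
eigenfunction indices shift down by one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BasisSet",
    "indicator_basis",
    "monomial_basis",
    "evaluate",
    "remove_mean",
]


@dataclass(frozen=True)
class BasisSet:
    n: int
    kind: str  # "indicator" | "monomial"
    edges: np.ndarray | None = None  # indicator cell edges (ascending)
    dim_axis: int = 0  # axis the indicator partition lives on
    exponents: tuple | None = None  # monomial exponent tuples
    mean_removed: bool = False
    means: np.ndarray | None = None

    def to_spec(self) -> dict:
        """JSON-serializable description (round-trips via from_spec)."""
        spec = {"kind": self.kind, "mean_removed": self.mean_removed}
        if self.kind == "indicator":
            spec["edges"] = list(map(float, self.edges))
            spec["dim_axis"] = self.dim_axis
        else:
            spec["exponents"] = [list(e) for e in self.exponents]
        if self.means is not None:
            spec["means"] = list(map(float, self.means))
        return spec

    @staticmethod
    def from_spec(spec: dict | str) -> "BasisSet":
        if isinstance(spec, str):
            spec = json.loads(spec)
        if spec["kind"] == "indicator":
            b = indicator_basis(spec["edges"], dim_axis=spec.get("dim_axis", 0))
        else:
            b = monomial_basis([tuple(e) for e in spec["exponents"]])
        if spec.get("means") is not None:
            means = np.asarray(spec["means"], dtype=float)
            b = BasisSet(**{**b.__dict__, "mean_removed": True, "means": means})
        return b


def indicator_basis(edges, dim_axis: int = 0) -> BasisSet:
    """Indicator functions on the half-open cells [e_i, e_{i+1}).

    The rightmost cell is closed.  Points outside [e_0, e_last] evaluate
    to an all-zero row (rare excursions should not abort long runs).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("need at least 2 edges")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing")
    return BasisSet(n=len(edges) - 1, kind="indicator", edges=edges,
                    dim_axis=dim_axis)


def uniform_indicator_basis(n: int, lo: float = -3.0, hi: float = 3.0,
                            dim_axis: int = 0,
                            extend: float | None = None) -> BasisSet:
    """n equal-width indicator cells on [lo, hi].

    With `extend`, the outermost edges are moved to -extend/+extend so the
    partition covers rare excursions beyond [lo, hi] (the usual Markov
    state model convention of partitioning the whole sampled range).
    """
    edges = np.linspace(lo, hi, n + 1)
    if extend is not None:
        if extend <= max(abs(lo), abs(hi)):
            raise ValueError("extend must exceed the core interval")
        edges[0], edges[-1] = -extend, extend
    return indicator_basis(edges, dim_axis=dim_axis)


def gaussian_quantile_indicator_basis(n: int, clip: float = 7.5,
                                      dim_axis: int = 0) -> BasisSet:
    """n equal-probability indicator cells under a standard normal law.

    Cell edges are standard-normal quantiles (the outermost clipped to
    -clip/+clip), so every cell carries stationary mass 1/n.  This is the
    indicator analogue of the usual data-density-adapted Markov state
    model partition: no cell is starved of samples, at the price of wide
    cells in the tails.
    """
    from scipy.stats import norm

    edges = norm.ppf(np.linspace(0.0, 1.0, n + 1))
    edges[0], edges[-1] = -clip, clip
    return indicator_basis(edges, dim_axis=dim_axis)


def monomial_basis(exponents) -> BasisSet:
    """Monomials x -> prod_i x_i^{e_i} for each exponent tuple."""
    exps = [tuple(int(v) for v in e) for e in exponents]
    if len(set(exps)) != len(exps):
        raise ValueError("duplicate exponent tuples")
    if any(v < 0 for e in exps for v in e):
        raise ValueError("exponents must be nonnegative")
    dims = {len(e) for e in exps}
    if len(dims) != 1:
        raise ValueError("all exponent tuples must have the same length")
    return BasisSet(n=len(exps), kind="monomial", exponents=tuple(exps))


def quadratic_monomials_2d() -> BasisSet:
    """The 2D quadratic set {1, x1, x2, x1^2, x1 x2, x2^2}."""
    return monomial_basis(
        [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]
    )


def evaluate(basis: BasisSet, points: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions: returns (frames, n)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite values")

    if basis.kind == "indicator":
        x = pts[:, basis.dim_axis]
        cell = np.searchsorted(basis.edges, x, side="right") - 1
        # close the rightmost cell
        cell[x == basis.edges[-1]] = basis.n - 1
        out = np.zeros((len(x), basis.n))
        inside = (cell >= 0) & (cell < basis.n)
        out[np.nonzero(inside)[0], cell[inside]] = 1.0
    elif basis.kind == "monomial":
        dim = len(basis.exponents[0])
        if pts.shape[1] != dim:
            raise ValueError(
                f"points have dim {pts.shape[1]}, basis expects {dim}"
            )
        out = np.empty((pts.shape[0], basis.n))
        for j, e in enumerate(basis.exponents):
            col = np.ones(pts.shape[0])
            for axis, p in enumerate(e):
                if p:
                    col = col * pts[:, axis] ** p
            out[:, j] = col
    else:
        raise ValueError(f"unknown basis kind {basis.kind!r}")

    if basis.mean_removed:
        out = out - basis.means[None, :]
    return out


def remove_mean(basis: BasisSet, points: np.ndarray,
                weights: np.ndarray | None = None) -> BasisSet:
    """Return a copy of `basis` with means (under `points`) subtracted.

    Means are the empirical averages over `points`, or the
    `weights`-weighted averages (e.g. stationary grid weights) when given.
    Afterwards the constant eigenfunction is intentionally absent from
    VAC output and subspace indices shift down by one.
    """
    raw = BasisSet(**{**basis.__dict__, "mean_removed": False, "means": None})
    vals = evaluate(raw, points)
    if weights is None:
        means = vals.mean(axis=0)
    else:
        wts = np.asarray(weights, dtype=float)
        means = vals.T @ (wts / wts.sum())
    return BasisSet(**{**basis.__dict__, "mean_removed": True, "means": means})
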