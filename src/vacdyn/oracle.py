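"""Grid discretization of the diffusion generator: the exact reference side.

For a reversible diffusion with generator

    A f = (1/2) e^{U} div( a e^{-U} grad f ),

this module builds a finite-difference discretization L on a tensor-product
grid such that detailed balance holds *exactly*: with M = diag(mu_h) the
discrete stationary weights, M L is symmetric by construction.  The matrix
L is assembled from a discrete Dirichlet form

    E(f, g) = (1/2) sum over faces/cells  w  grad f . a grad g,

with face/cell weights w = exp(-U); then L = -M^{-1} K with K = K^T >= 0.
This guarantees L 1 = 0, mu_h^T L = 0 and a real, nonnegative spectrum --
the properties every bound downstream relies on.  Boundary fluxes are
simply omitted (reflecting / zero-flux), which preserves mu_h exactly.

The axis-aligned second-derivative terms use standard two-point face
stencils; the mixed term a_12 d1 d2 (2D only) is discretized with
cell-centered averaged gradients, which keeps K exactly symmetric while
remaining second-order accurate.

From the eigendecomposition of the symmetrized operator we obtain the
reference rates sigma_i and mu-orthonormal eigenfunctions eta_i, and from
those the exact correlation matrices C(0), C(tau) for any basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .models import SdeModel

__all__ = [
    "GridDomain",
    "DiscreteGenerator",
    "SpectralReference",
    "make_grid",
    "discretize",
    "reference_spectrum",
    "exact_correlations",
    "exact_vac_input",
    "default_domain",
]


@dataclass(frozen=True)
class GridDomain:
    """Tensor-product grid: node coordinates and quadrature weights per axis."""

    axes: tuple  # tuple of 1D node-coordinate arrays
    spacings: tuple  # per-axis spacing (uniform)

    def __post_init__(self):
        for ax in self.axes:
            if not np.all(np.diff(ax) > 0):
                raise ValueError("grid nodes must be strictly increasing")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple:
        return tuple(len(ax) for ax in self.axes)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacings))

    def nodes(self) -> np.ndarray:
        """All node coordinates, shape (n_nodes, ndim), C-order raveling."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)


def make_grid(bounds, n_nodes) -> GridDomain:
    """Uniform grid; `bounds` is a list of (lo, hi), `n_nodes` per axis."""
    bounds = list(bounds)
    if np.isscalar(n_nodes):
        n_nodes = [int(n_nodes)] * len(bounds)
    axes, spacings = [], []
    for (lo, hi), n in zip(bounds, n_nodes):
        ax = np.linspace(lo, hi, int(n))
        axes.append(ax)
        spacings.append(ax[1] - ax[0])
    return GridDomain(axes=tuple(axes), spacings=tuple(spacings))


def default_domain(model: SdeModel) -> GridDomain:
    """Default oracle grid covering essentially all stationary mass."""
    if model.name == "ou1d":
        return make_grid([(-7.5, 7.5)], [750])
    if model.name == "doublewell2d":
        return make_grid([(-2.0, 2.0), (-7.5, 7.5)], [170, 118])
    raise ValueError(f"no default domain for model {model.name!r}")


@dataclass(frozen=True)
class DiscreteGenerator:
    """Sparse generator L with exact discrete detailed balance."""

    L: sp.spmatrix  # (n_nodes, n_nodes), L @ 1 = 0
    mu: np.ndarray  # stationary weights, sum to 1
    domain: GridDomain
    stiffness: sp.spmatrix  # symmetric K with L = -(1/2) Mtilde^{-1} K
    model_name: str = ""


class BoundaryMassError(ValueError):
    """Stationary density is not negligible at the domain boundary."""


def discretize(
    model: SdeModel, domain: GridDomain | None = None, boundary_tol: float = 1e-12
) -> DiscreteGenerator:
    """Discretize the generator of `model` on `domain`.

    Raises :class:`BoundaryMassError` when exp(-U) at the boundary exceeds
    `boundary_tol` relative to its maximum, since a reflecting wall through
    non-negligible mass would distort the spectrum.
    """
    if domain is None:
        domain = default_domain(model)
    if domain.ndim != model.dim:
        raise ValueError("domain dimension does not match model")

    nodes = domain.nodes()
    U = model.potential(nodes).reshape(domain.shape)
    w = np.exp(-(U - U.min()))  # unnormalized stationary density on nodes

    bmask = np.zeros(domain.shape, dtype=bool)
    for axis in range(domain.ndim):
        idx = [slice(None)] * domain.ndim
        for edge in (0, -1):
            idx[axis] = edge
            bmask[tuple(idx)] = True
    if w[bmask].max() > boundary_tol:
        raise BoundaryMassError(
            f"exp(-U) at boundary is {w[bmask].max():.2e} of max "
            f"(tolerance {boundary_tol:.0e}); enlarge the domain"
        )

    a = model.a
    n = domain.n_nodes
    shape = domain.shape

    def lin(index_arrays):
        return np.ravel_multi_index(index_arrays, shape)

    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i.ravel())
        cols.append(j.ravel())
        vals.append(v.ravel())

    vol = domain.cell_volume

    # axis-aligned terms: face-centered two-point stencils
    for axis in range(domain.ndim):
        h = domain.spacings[axis]
        sl_lo = [slice(None)] * domain.ndim
        sl_hi = [slice(None)] * domain.ndim
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        w_face = np.sqrt(w[tuple(sl_lo)] * w[tuple(sl_hi)])  # e^{-U} at face
        coef = a[axis, axis] * w_face * vol / h**2
        idx = np.indices(shape)
        i_lo = lin(tuple(ix[tuple(sl_lo)] for ix in idx))
        i_hi = lin(tuple(ix[tuple(sl_hi)] for ix in idx))
        add(i_lo, i_lo, coef)
        add(i_hi, i_hi, coef)
        add(i_lo, i_hi, -coef)
        add(i_hi, i_lo, -coef)

    # mixed term (2D): cell-centered averaged gradients, exactly symmetric
    if domain.ndim == 2 and a[0, 1] != 0.0:
        h1, h2 = domain.spacings
        w_cell = 0.25 * (w[:-1, :-1] + w[1:, :-1] + w[:-1, 1:] + w[1:, 1:])
        coef = a[0, 1] * w_cell * vol
        idx = np.indices(shape)
        c00 = lin(tuple(ix[:-1, :-1] for ix in idx))
        c10 = lin(tuple(ix[1:, :-1] for ix in idx))
        c01 = lin(tuple(ix[:-1, 1:] for ix in idx))
        c11 = lin(tuple(ix[1:, 1:] for ix in idx))
        # d1 f at cell center = (f10 - f00 + f11 - f01) / (2 h1)
        # d2 f at cell center = (f01 - f00 + f11 - f10) / (2 h2)
        # contribution coef * 2 * (d1 f)(d2 g), symmetrized below with K^T
        scale = 1.0 / (4.0 * h1 * h2)
        for (ia, va) in zip((c10, c00, c11, c01), (1.0, -1.0, 1.0, -1.0)):
            for (ib, vb) in zip((c01, c00, c11, c10), (1.0, -1.0, 1.0, -1.0)):
                add(ia, ib, 2.0 * coef * va * vb * scale)

    K = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    K = 0.5 * (K + K.T)

    mtilde = (w * vol).ravel()
    L = -0.5 * sp.diags(1.0 / mtilde) @ K
    mu = mtilde / mtilde.sum()
    return DiscreteGenerator(
        L=L.tocsr(), mu=mu, domain=domain, stiffness=K.tocsr(),
        model_name=model.name,
    )


@dataclass(frozen=True)
class SpectralReference:
    """Reference rates and mu-orthonormal grid eigenfunctions of -L."""

    rates: np.ndarray  # sigma_1 <= ... <= sigma_r, sigma_1 = 0
    eigenfunctions: np.ndarray  # (n_nodes, r), columns eta_i
    mu: np.ndarray
    domain: GridDomain
    model_name: str = ""

    @property
    def r(self) -> int:
        return len(self.rates)

    def inner(self, f: np.ndarray, g: np.ndarray) -> np.ndarray:
        """L^2(mu) inner product(s); f, g node vectors or (nodes, k) arrays."""
        return np.atleast_2d(f).reshape(len(self.mu), -1).T @ (
            self.mu[:, None] * np.atleast_2d(g).reshape(len(self.mu), -1)
        )

    def eigenvalues(self, tau: float) -> np.ndarray:
        """Transition-operator eigenvalues exp(-sigma_i tau)."""
        return np.exp(-self.rates * tau)

    def save(self, path: str) -> None:
        np.savez(
            path,
            rates=self.rates,
            eigenfunctions=self.eigenfunctions,
            mu=self.mu,
            axes=np.array(len(self.domain.axes), dtype=int),
            **{f"axis{i}": ax for i, ax in enumerate(self.domain.axes)},
            model_name=self.model_name,
        )

    @staticmethod
    def load(path: str) -> "SpectralReference":
        with np.load(path, allow_pickle=False) as z:
            naxes = int(z["axes"])
            axes = tuple(z[f"axis{i}"] for i in range(naxes))
            dom = GridDomain(
                axes=axes, spacings=tuple(ax[1] - ax[0] for ax in axes)
            )
            return SpectralReference(
                rates=z["rates"],
                eigenfunctions=z["eigenfunctions"],
                mu=z["mu"],
                domain=dom,
                model_name=str(z["model_name"]),
            )


def reference_spectrum(gen: DiscreteGenerator, r: int) -> SpectralReference:
    """The r smallest rates/eigenfunctions of -L, mu-orthonormal.

    Solved through the symmetric similarity transform
    M^{1/2} (-L) M^{-1/2} = (1/2) Mtilde^{-1/2} K Mtilde^{-1/2}, dense for
    small grids and sparse shift-invert Lanczos otherwise.
    """
    n = gen.L.shape[0]
    if not (1 <= r <= n):
        raise ValueError("need 1 <= r <= n_nodes")
    d = np.asarray(gen.mu)
    dinv = 1.0 / np.sqrt(d)
    S = sp.diags(np.sqrt(d)) @ (-gen.L) @ sp.diags(dinv)
    S = 0.5 * (S + S.T)  # symmetric to roundoff by detailed balance

    if r > n // 4 or n <= 1500:
        evals, evecs = np.linalg.eigh(S.toarray())
        evals, evecs = evals[:r], evecs[:, :r]
    else:
        evals, evecs = spla.eigsh(S.tocsc(), k=r, sigma=-1e-2, which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]

    evals = np.clip(evals, 0.0, None)
    evals[0] = 0.0
    eta = evecs * dinv[:, None]  # back-transform; mu-orthonormal
    # deterministic sign: largest-|.| entry positive; eta_1 = +1
    for i in range(r):
        jmax = np.argmax(np.abs(eta[:, i]))
        if eta[jmax, i] < 0:
            eta[:, i] = -eta[:, i]
    eta[:, 0] = 1.0
    return SpectralReference(
        rates=evals, eigenfunctions=eta, mu=np.asarray(gen.mu),
        domain=gen.domain, model_name=gen.model_name,
    )


class TruncationError(RuntimeError):
    """Spectral truncation cannot represent the basis accurately."""


def exact_correlations(
    ref: SpectralReference,
    basis_values: np.ndarray,
    tau: float,
    rel_tol: float = 1e-6,
):
    """Exact C(0) and C(tau) for basis functions given by node values.

    C(tau)_ij = sum_l exp(-sigma_l tau) <eta_l, phi_i> <eta_l, phi_j> over
    the reference spectrum, and C(0) is the full (untruncated) Gram
    matrix.  Adequacy of the truncation is checked through the
    completeness defect d_i = C(0)_ii - sum_l <eta_l, phi_i>^2: by
    Cauchy--Schwarz the omitted tail of C(tau)_ij is at most
    exp(-sigma_r tau) sqrt(d_i d_j), which must stay below `rel_tol`
    relative to the diagonal scale of C(0).

    Returns a :class:`vacdyn.core.CorrelationPair`.
    """
    from .core import CorrelationPair

    if tau < 0:
        raise ValueError("tau must be >= 0")
    B = np.atleast_2d(np.asarray(basis_values, dtype=float))
    if B.shape[0] != len(ref.mu):
        raise ValueError("basis_values must be evaluated on the oracle nodes")
    overlaps = ref.eigenfunctions.T @ (ref.mu[:, None] * B)  # (r, n)
    C0 = B.T @ (ref.mu[:, None] * B)
    C0 = 0.5 * (C0 + C0.T)
    defect = np.clip(np.diag(C0) - np.sum(overlaps**2, axis=0), 0.0, None)
    scale = max(np.diag(C0).max(), 1e-300)
    tail = np.exp(-ref.rates[-1] * tau) * defect.max()
    if tau > 0 and tail > rel_tol * scale:
        raise TruncationError(
            f"spectral-tail bound {tail:.2e} exceeds {rel_tol:.0e} x max "
            f"diag C(0) at tau={tau}; increase the reference rank r"
        )
    lam = np.exp(-ref.rates * tau)
    Ct = (overlaps * lam[:, None]).T @ overlaps
    Ct = 0.5 * (Ct + Ct.T)
    return CorrelationPair(C0=C0, Ct=Ct, tau=tau, n_frames_used=0, source="oracle")


def exact_vac_input(ref: SpectralReference, basis, tau: float, rel_tol: float = 1e-8):
    """Convenience: exact correlations for a :class:`vacdyn.basis.BasisSet`."""
    from .basis import evaluate

    B = evaluate(basis, ref.domain.nodes())
    return exact_correlations(ref, B, tau, rel_tol=rel_tol)
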