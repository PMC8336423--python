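"""Approximation-error bounds and long-lag limits on the grid oracles."""

import numpy as np
import pytest

from vacdyn.basis import evaluate, uniform_indicator_basis
from vacdyn.bounds import (ProjectionDependenceError, idealized_vac,
                           lag_independent_bound, long_lag_limits,
                           offdiagonal_operator_norm,
                           orthogonalized_projections,
                           rayleigh_ritz_eigenvalue_bound,
                           rayleigh_ritz_subspace_bound, sharp_subspace_bound)


@pytest.fixture(scope="module")
def ou_basis20(ou_ref):
    return evaluate(uniform_indicator_basis(20, extend=7.5),
                    ou_ref.domain.nodes())


class TestOrthogonalizedProjections:
    def test_eigenbasis_projection_is_identity(self, ou_ref):
        B = ou_ref.eigenfunctions[:, :4]
        qset = orthogonalized_projections(ou_ref, B, p=4)
        # q_i = eta_i and diagonal overlaps are 1
        assert np.diag(qset.overlaps)[:4] == pytest.approx(np.ones(4), abs=1e-8)
        for i in range(4):
            diff = qset.q[:, i] - ou_ref.eigenfunctions[:, i]
            assert np.sqrt(diff @ (ou_ref.mu * diff)) < 1e-7

    def test_constant_in_basis_gives_q1_one(self, ou_ref, ou_basis20):
        qset = orthogonalized_projections(ou_ref, ou_basis20, p=1)
        assert qset.q[:, 0] == pytest.approx(np.ones(len(ou_ref.mu)), abs=1e-8)

    def test_orthonormality_and_membership(self, ou_ref, ou_basis20):
        qset = orthogonalized_projections(ou_ref, ou_basis20, p=5)
        G = qset.q.T @ (ou_ref.mu[:, None] * qset.q)
        assert G == pytest.approx(np.eye(5), abs=1e-8)

    def test_linear_dependence_raises(self, ou_ref):
        # eta_2 is orthogonal to span{eta_1, eta_5}, so its projection
        # vanishes and the recursion is undefined
        B = ou_ref.eigenfunctions[:, [0, 4]]
        with pytest.raises(ProjectionDependenceError):
            orthogonalized_projections(ou_ref, B, p=2)


def test_long_lag_eigenvalue_limit(ou_ref, ou_basis20):
    # lambda_k e^{sigma_k tau} -> <eta_k, q_k>^2, within 1% at tau = 8
    qset = orthogonalized_projections(ou_ref, ou_basis20, p=4)
    sol, _ = idealized_vac(ou_ref, ou_basis20, 8.0)
    for k in (1, 2, 3):
        obs = sol.eigenvalues[k - 1] * np.exp(ou_ref.rates[k - 1] * 8.0)
        lim = qset.overlaps[k - 1, k - 1] ** 2
        assert obs == pytest.approx(lim, rel=0.01)


def test_long_lag_subspace_limit_and_rate(ou_ref):
    # an asymmetric partition: with a symmetric basis the overlap
    # <eta_3, q_2> vanishes by parity and the limit degenerates to 0
    edges = np.linspace(-2.6, 3.4, 21)
    edges[0], edges[-1] = -7.5, 7.5
    from vacdyn.basis import indicator_basis

    basis = evaluate(indicator_basis(edges), ou_ref.domain.nodes())
    k = 2
    qset = orthogonalized_projections(ou_ref, basis, p=k + 1)
    taus = np.linspace(3.0, 6.0, 7)
    out = long_lag_limits(ou_ref, basis, qset, taus, k)
    assert out["gaps_ok"]
    # scaled distance converges to the predicted overlap quotient
    assert out["table"]["df_scaled"][-1] == pytest.approx(
        out["df_limit"], rel=0.05
    )
    # |observed - limit| for the eigenvalue ratio shrinks with tau
    err = np.abs(out["table"]["eig_ratio"] - out["eig_limit"])
    assert np.all(np.diff(err) <= 1e-12)
    # d_F(Gamma, Q) decays log-linearly at rate sigma_{k+1} - sigma_k
    slope = np.polyfit(taus, np.log(out["table"]["df_gamma_q"]), 1)[0]
    expect = -(ou_ref.rates[k] - ou_ref.rates[k - 1])
    assert slope == pytest.approx(expect, rel=0.10)


class TestEigenvalueBound:
    def test_invariant_basis_collapses_bounds(self, ou_ref):
        B = ou_ref.eigenfunctions[:, :3]
        rep = rayleigh_ritz_eigenvalue_bound(ou_ref, B, 0.5, 2)
        assert rep.lower == pytest.approx(1.0, abs=1e-8)
        assert rep.observed == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_basis_vacuous_lower_bound(self, ou_ref):
        # basis orthogonal to eta_1..2: d_2 = 1, lower bound 0
        B = ou_ref.eigenfunctions[:, 4:7]
        rep = rayleigh_ritz_eigenvalue_bound(ou_ref, B, 0.5, 2)
        assert rep.lower == pytest.approx(0.0, abs=1e-8)

    def test_holds_on_indicator_sweep(self, ou_ref, ou_basis20):
        for tau in (0.1, 0.5, 1.0, 2.0, 3.0):
            for k in (1, 2, 3):
                rep = rayleigh_ritz_eigenvalue_bound(ou_ref, ou_basis20, tau, k)
                assert rep.lower - 1e-10 <= rep.observed <= rep.upper + 1e-10


def test_subspace_bound_invariant_basis_zero_offdiagonal(ou_ref):
    B = ou_ref.eigenfunctions[:, :4]
    assert offdiagonal_operator_norm(ou_ref, B, 1.0) < 1e-6
    rep = rayleigh_ritz_subspace_bound(ou_ref, B, 1.0, 2)
    assert rep.observed == pytest.approx(1.0)  # 0/0 convention


def test_classical_vs_sharp_bound_large_lag_behavior(ou_ref, ou_basis20):
    """The classical multiplier diverges with tau (for k = 3 the spectral
    gap in its denominator closes faster than the off-block norm decays);
    the sharp multiplier tends to 1 and the observed ratio stays bounded."""
    k = 3
    taus = np.linspace(0.5, 4.0, 8)
    classical = [rayleigh_ritz_subspace_bound(ou_ref, ou_basis20, t, k).upper
                 for t in taus]
    sharp = [sharp_subspace_bound(ou_ref, ou_basis20, t, k).upper
             for t in taus]
    assert np.all(np.diff(classical[3:]) > 0)  # divergence
    assert np.all(np.diff(sharp[3:]) < 0) and sharp[-1] < 1.01  # -> 1
    # observed ratio stays bounded throughout
    obs = [rayleigh_ritz_subspace_bound(ou_ref, ou_basis20, t, k).observed
           for t in taus]
    assert max(obs) < 10.0


def test_sharp_bound_arithmetic_and_applicability(ou_ref, ou_basis20):
    # printed formula: lambda_k = 0.5, e^{-sigma_{k+1} tau} = 0.25 -> 1.25
    assert 1 + 0.25 * (0.25 / (0.5 - 0.25)) ** 2 == pytest.approx(1.25)
    rep = sharp_subspace_bound(ou_ref, ou_basis20, 2.0, 2)
    assert rep.applicable
    assert 1.0 - 1e-10 <= rep.observed <= rep.upper + 1e-10


def test_approximation_error_split(ou_ref, ou_basis20):
    # d_F(Gamma, H) <= d_F(Q, H) + d_F(Gamma, Q) at several lags
    from vacdyn.subspaces import FunctionSubspace, projection_distance

    k = 3
    qset = orthogonalized_projections(ou_ref, ou_basis20, p=k)
    H = FunctionSubspace(ou_ref.eigenfunctions[:, :k], ou_ref.mu)
    Q = FunctionSubspace(qset.q[:, :k], ou_ref.mu)
    for tau in (0.3, 0.8, 1.5):
        _, Gamma = idealized_vac(ou_ref, ou_basis20, tau)
        G = FunctionSubspace(Gamma[:, :k], ou_ref.mu)
        lhs = projection_distance(G, H)
        rhs = projection_distance(Q, H) + projection_distance(G, Q)
        assert lhs <= rhs + 1e-10


class TestLagIndependentBound:
    def test_j_equals_one_reduces_to_basis_distance(self, ou_ref, ou_basis20):
        out = lag_independent_bound(ou_ref, ou_basis20, 1, 3)
        assert out["holds"]

    def test_invariant_basis_both_sides_zero(self, ou_ref):
        B = ou_ref.eigenfunctions[:, :4]
        out = lag_independent_bound(ou_ref, B, 2, 3)
        assert out["left"] == pytest.approx(0.0, abs=1e-8)
        assert out["right"] == pytest.approx(0.0, abs=1e-8)

    def test_refinement_drives_both_sides_to_zero(self, ou_ref):
        vals = []
        for n in (10, 30, 90):
            B = evaluate(uniform_indicator_basis(n, -5, 5),
                         ou_ref.domain.nodes())
            out = lag_independent_bound(ou_ref, B, 2, 3)
            assert out["holds"]
            vals.append((out["left"], out["right"]))
        lefts, rights = zip(*vals)
        assert lefts[-1] < lefts[0] and rights[-1] < rights[0]
        assert rights[-1] < 1e-2
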