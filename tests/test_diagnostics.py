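"""Loss matrix, condition number, and the plug-in estimation-error MSE."""

import numpy as np
import pytest

from vacdyn.basis import evaluate, indicator_basis, uniform_indicator_basis
from vacdyn.core import CorrelationPair, solve_vac
from vacdyn.diagnostics import (asymptotic_mse, condition_number, loss_matrix,
                                long_run_variance, minimum_condition_number)
from vacdyn.models import Trajectory
from vacdyn.oracle import exact_correlations
from vacdyn.subspaces import FunctionSubspace, projection_distance


def test_loss_matrix_vanishes_on_own_fit(rng):
    A = rng.standard_normal((5, 5))
    C0 = A @ A.T + 5 * np.eye(5)
    S = rng.standard_normal((5, 5))
    corr = CorrelationPair(C0=C0, Ct=0.5 * (S + S.T), tau=1.0)
    sol = solve_vac(corr)
    L = loss_matrix(corr, sol).entries
    assert np.abs(L).max() < 1e-10


@pytest.fixture(scope="module")
def ou_ideal(ou_ref):
    B = evaluate(uniform_indicator_basis(10, extend=7.0),
                 ou_ref.domain.nodes())
    corr = exact_correlations(ou_ref, B, 0.5)
    return corr, solve_vac(corr)


def richardson_errors(corr, sol, E, eps, k=2, j=1, kk=3):
    """First-order-prediction remainders for a perturbation eps*E."""
    pert = CorrelationPair(C0=corr.C0, Ct=corr.Ct + eps * E, tau=corr.tau)
    psol = solve_vac(pert)
    L = loss_matrix(pert, sol).entries
    # eigenvalue remainder
    eig_rem = abs((psol.eigenvalues[k - 1] - sol.eigenvalues[k - 1])
                  - L[k - 1, k - 1])
    # subspace remainder: first-order formula vs direct distance
    lam = sol.eigenvalues
    pred = 0.0
    for l in range(sol.m):
        if j - 1 <= l <= kk - 1:
            continue
        for m in range(j - 1, kk):
            pred += (L[l, m] / (lam[l] - lam[m])) ** 2
    pred = np.sqrt(pred)
    dU = FunctionSubspace(psol.V[:, j - 1 : kk], corr.C0)
    dW = FunctionSubspace(sol.V[:, j - 1 : kk], corr.C0)
    sub_rem = abs(projection_distance(dU, dW) - pred)
    return eig_rem, sub_rem


def test_first_order_formulas_have_quadratic_remainder(ou_ideal, rng):
    """Richardson check: halving eps divides the remainder by ~4."""
    corr, sol = ou_ideal
    E = rng.standard_normal((corr.n, corr.n))
    E = 0.5 * (E + E.T)
    E /= np.linalg.norm(E)
    e1, s1 = richardson_errors(corr, sol, E, 1e-3)
    e2, s2 = richardson_errors(corr, sol, E, 5e-4)
    assert e1 / e2 == pytest.approx(4.0, abs=0.5)
    assert s1 / s2 == pytest.approx(4.0, abs=0.5)


class TestConditionNumber:
    def test_direct_substitution(self):
        lam = [1.0, 0.8, 0.4, 0.2]
        assert condition_number(lam, 1, 2) == pytest.approx(2.5)
        # conventions lambda_0 = inf, lambda_{n+1} = -inf
        assert condition_number(lam, 1, 4) == pytest.approx(0.0, abs=1e-12)
        assert condition_number(lam, 2, 2) == pytest.approx(1 / 0.2)

    def test_bad_range(self):
        with pytest.raises(ValueError):
            condition_number([1.0, 0.5], 2, 1)

    def test_invariant_to_correlation_scaling(self, rng):
        A = rng.standard_normal((6, 6))
        C0 = A @ A.T + 6 * np.eye(6)
        S = rng.standard_normal((6, 6))
        Ct = 0.5 * (S + S.T)
        k1 = condition_number(
            solve_vac(CorrelationPair(C0=C0, Ct=Ct, tau=1.0)).eigenvalues, 1, 2)
        k2 = condition_number(
            solve_vac(CorrelationPair(C0=7.3 * C0, Ct=7.3 * Ct,
                                      tau=1.0)).eigenvalues, 1, 2)
        assert k1 == pytest.approx(k2, rel=1e-10)

    def test_minimum_report(self, ou_ref):
        B = evaluate(uniform_indicator_basis(10, extend=7.0),
                     ou_ref.domain.nodes())
        sols = [solve_vac(exact_correlations(ou_ref, B, t))
                for t in (0.2, 0.5, 1.0)]
        rep = minimum_condition_number(sols, 1, 3)
        assert rep.kappa_min == np.min(rep.kappas)
        assert np.all(rep.kappas > 0)


def test_long_run_variance_iid_limit(rng):
    # for white noise the long-run variance is just the variance
    x = rng.standard_normal((3, 20000))
    lrv = long_run_variance(x, window=1)
    assert lrv == pytest.approx(x.var(axis=1), rel=0.02)


def test_mse_zero_for_constant_eigenfunctions():
    from vacdyn.core import VacSolution

    states = np.tile(np.array([0.0, 1.0, 2.0]), 400)[:, None]
    tr = Trajectory(states=states, delta=1.0, seed=0)
    basis = indicator_basis([-0.5, 0.5, 1.5, 2.5])
    # gamma_1 = sum of all indicators = 1 on every sampled state
    sol = VacSolution(tau=1.0, eigenvalues=np.array([1.0]),
                      V=np.ones((3, 1)), retained_rank=1)
    rep = asymptotic_mse(tr, basis, sol, 1, 1, window=5)
    assert rep.eigenvalue_variances[1] == pytest.approx(0.0, abs=1e-20)
    assert rep.root_mse == 0.0


def test_mse_scales_inversely_with_T(rng):
    from vacdyn.models import make_ou1d, simulate_ensemble
    from vacdyn.core import empirical_correlations

    basis = uniform_indicator_basis(8, extend=7.0)
    tau = 0.5
    rmses = {}
    # T large enough for the asymptotic 1/sqrt(T) regime
    for T in (1000.0, 4000.0):
        trs = simulate_ensemble(make_ou1d(), 8, T, 0.05, sub_steps=2, seed=17)
        vals = []
        for tr in trs:
            sol = solve_vac(empirical_correlations(tr, basis, tau))
            vals.append(asymptotic_mse(tr, basis, sol, 1, 3).root_mse)
        rmses[T] = np.median(vals)
    assert rmses[1000.0] / rmses[4000.0] == pytest.approx(2.0, rel=0.20)


# --- 3-state reversible chain: brute-force ensemble oracle ---------------

from markov_chain import P3, PI3, simulate_chains


def test_chain_is_reversible():
    flux = PI3[:, None] * P3
    assert flux == pytest.approx(flux.T)
    assert PI3 @ P3 == pytest.approx(PI3)


def test_eigenvalue_variance_on_3state_chain(rng):
    """Plug-in Var(lambda_hat) vs the spread over replicate chains."""
    basis = indicator_basis([-0.5, 0.5, 1.5, 2.5])
    n_steps, n_chains = 2000, 300
    states = simulate_chains(n_chains, n_steps, rng)
    from vacdyn.core import empirical_correlations

    lam2, var2 = [], []
    for c in range(n_chains):
        tr = Trajectory(states=states[c].astype(float)[:, None], delta=1.0,
                        seed=c)
        sol = solve_vac(empirical_correlations(tr, basis, 1.0))
        lam2.append(sol.eigenvalues[1])
        var2.append(asymptotic_mse(tr, basis, sol, 2, 2).eigenvalue_mse[2])
    assert np.mean(var2) == pytest.approx(np.var(lam2), rel=0.30)
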