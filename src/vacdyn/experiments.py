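"""Scripted benchmark studies: OU basis/data trade-off and the 2D
double-well subspace comparison.

Two OU trials estimate span(eta_1, eta_2, eta_3) of dX = -X dt + sqrt(2) dW
with indicator bases, trading basis size against trajectory length:

    trial 1: n = 20 cells, T = 1e4   (approximation error dominates)
    trial 2: n = 50 cells, T = 500   (estimation error dominates)

The double-well study estimates span(eta_1, eta_2) and
span(eta_1, eta_2, eta_3) of the 2D metastable diffusion from T = 500
trajectories with the quadratic monomial basis {1, x1, x2, x1^2, x1 x2,
x2^2}, contrasting a well-conditioned with an ill-conditioned subspace.

Every replicate/lag produces the full error decomposition (total,
approximation, estimation, all as projection distances in L^2(mu)
against the grid oracle), the plug-in root mean squared estimation
error, implied timescales, and condition numbers.  All randomness flows
from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import basis as basis_mod
from .basis import BasisSet, evaluate, gaussian_quantile_indicator_basis
from .core import CorrelationPair, empirical_correlations, solve_vac
from .diagnostics import asymptotic_mse, condition_number
from .models import make_doublewell2d, make_ou1d, simulate_ensemble
from .oracle import (SpectralReference, discretize, exact_correlations,
                     reference_spectrum)
from .subspaces import FunctionSubspace, projection_distance

__all__ = [
    "ExperimentConfig",
    "ErrorCurves",
    "ou_trial_config",
    "doublewell_config",
    "run_experiment",
    "run_ou_trial",
    "run_doublewell",
    "implied_timescale_report",
]

DEFAULT_TAU_GRID = np.round(np.arange(1, 31) * 0.05, 10)  # 0.05 ... 1.5


@dataclass(frozen=True)
class ExperimentConfig:
    model_name: str
    basis: BasisSet
    n_replicates: int = 30
    T: float = 1e4
    delta: float = 0.05
    sub_steps: int = 5
    burn_in: float = 0.0
    tau_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TAU_GRID.copy())
    subspace: tuple = (1, 3)
    seed: int = 0
    reference_rank: int | None = None

    def __post_init__(self):
        taus = np.asarray(self.tau_grid, dtype=float)
        lags = taus / self.delta
        if not np.allclose(lags, np.round(lags), atol=1e-9):
            raise ValueError("tau grid must lie on the frame lattice")
        object.__setattr__(self, "tau_grid", taus)


def ou_trial_config(trial: int, **overrides) -> ExperimentConfig:
    """Configs for the two OU trials (n=20/T=1e4 and n=50/T=500)."""
    if trial == 1:
        base = ExperimentConfig(
            model_name="ou1d",
            basis=gaussian_quantile_indicator_basis(20), T=1e4,
        )
    elif trial == 2:
        base = ExperimentConfig(
            model_name="ou1d",
            basis=gaussian_quantile_indicator_basis(50), T=500.0,
        )
    else:
        raise ValueError("trial must be 1 or 2")
    return replace(base, **overrides)


def doublewell_config(subspace=(1, 3), **overrides) -> ExperimentConfig:
    base = ExperimentConfig(
        model_name="doublewell2d",
        basis=basis_mod.quadratic_monomials_2d(),
        T=500.0,
        sub_steps=50,  # internal step 1e-3
        burn_in=50.0,
        subspace=tuple(subspace),
    )
    return replace(base, **overrides)


_MODELS = {"ou1d": make_ou1d, "doublewell2d": make_doublewell2d}
_REF_CACHE: dict = {}


def get_reference(model_name: str, rank: int | None = None) -> SpectralReference:
    """Grid oracle for a named model (cached within the process)."""
    if rank is None:
        rank = 600 if model_name == "ou1d" else 200
    key = (model_name, rank)
    if key not in _REF_CACHE:
        gen = discretize(_MODELS[model_name]())
        _REF_CACHE[key] = reference_spectrum(gen, rank)
    return _REF_CACHE[key]


@dataclass(frozen=True)
class ErrorCurves:
    config: ExperimentConfig
    tau_grid: np.ndarray
    approximation: np.ndarray  # (n_tau,), replicate-independent
    total: np.ndarray  # (n_rep, n_tau) raw per replicate
    estimation: np.ndarray  # (n_rep, n_tau)
    calculated_rmse: np.ndarray  # (n_rep, n_tau) plug-in root-MSE
    eigenvalues: np.ndarray  # (n_rep, n_tau, n_eig) leading estimates
    ideal_eigenvalues: np.ndarray  # (n_tau, n_eig)
    kappas: np.ndarray  # (n_tau,), idealized condition numbers

    @property
    def rms_total(self) -> np.ndarray:
        return np.sqrt(np.mean(self.total**2, axis=0))

    @property
    def rms_estimation(self) -> np.ndarray:
        return np.sqrt(np.mean(self.estimation**2, axis=0))

    @property
    def median_calculated_rmse(self) -> np.ndarray:
        return np.median(self.calculated_rmse, axis=0)

    @property
    def optimal_lag(self) -> float:
        """Arg-min of the RMS total-error curve over the lag grid."""
        return float(self.tau_grid[int(np.argmin(self.rms_total))])

    @property
    def kappa_min(self) -> float:
        return float(np.min(self.kappas))

    def rmse_crossing(self, level: float = 0.2) -> float:
        """Median-over-replicates first lag where plug-in root-MSE >= level."""
        crossings = []
        for row in self.calculated_rmse:
            above = np.nonzero(row >= level)[0]
            crossings.append(self.tau_grid[above[0]] if above.size else np.inf)
        return float(np.median(crossings))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.tau_grid,
                "rms_total": self.rms_total,
                "rms_estimation": self.rms_estimation,
                "approximation": self.approximation,
                "median_calc_rmse": self.median_calculated_rmse,
                "kappa": self.kappas,
            }
        )

    def summary(self) -> dict:
        return {
            "model": self.config.model_name,
            "subspace": list(self.config.subspace),
            "n_replicates": self.config.n_replicates,
            "T": self.config.T,
            "seed": self.config.seed,
            "optimal_lag": self.optimal_lag,
            "kappa_min": self.kappa_min,
            "max_median_calc_rmse": float(np.max(self.median_calculated_rmse)),
            "rmse_crossing_0.2": self.rmse_crossing(0.2),
        }


def run_experiment(cfg: ExperimentConfig, n_eig: int = 6) -> ErrorCurves:
    """Run one benchmark study: simulate, fit, decompose the error."""
    model = _MODELS[cfg.model_name]()
    ref = get_reference(cfg.model_name, cfg.reference_rank)
    nodes = ref.domain.nodes()
    Bgrid = evaluate(cfg.basis, nodes)
    j, k = cfg.subspace
    H = FunctionSubspace(ref.eigenfunctions[:, j - 1 : k], ref.mu)

    trajs = simulate_ensemble(
        model, cfg.n_replicates, cfg.T, cfg.delta,
        sub_steps=cfg.sub_steps, seed=cfg.seed, burn_in=cfg.burn_in,
    )

    n_tau, n_rep = len(cfg.tau_grid), cfg.n_replicates
    n_eig = min(n_eig, cfg.basis.n)
    approx = np.empty(n_tau)
    total = np.empty((n_rep, n_tau))
    estim = np.empty((n_rep, n_tau))
    calc = np.empty((n_rep, n_tau))
    eigs = np.full((n_rep, n_tau, n_eig), np.nan)
    ideal_eigs = np.full((n_tau, n_eig), np.nan)
    kappas = np.empty(n_tau)

    # idealized VAC once per lag
    ideal_subs = []
    for t_idx, tau in enumerate(cfg.tau_grid):
        ideal_sol = solve_vac(exact_correlations(ref, Bgrid, tau))
        ideal_subs.append(
            FunctionSubspace(Bgrid @ ideal_sol.V[:, j - 1 : k], ref.mu)
        )
        approx[t_idx] = projection_distance(ideal_subs[-1], H)
        m_i = min(n_eig, ideal_sol.m)
        ideal_eigs[t_idx, :m_i] = ideal_sol.eigenvalues[:m_i]
        kappas[t_idx] = condition_number(ideal_sol.eigenvalues, j, k)

    for r_idx, tr in enumerate(trajs):
        Y = evaluate(cfg.basis, tr.states)  # reused across all lags
        A0 = Y.T @ Y
        for t_idx, tau in enumerate(cfg.tau_grid):
            lag = int(round(tau / cfg.delta))
            At = Y[:-lag].T @ Y[lag:]
            corr = CorrelationPair(
                C0=A0 / Y.shape[0], Ct=0.5 * (At + At.T) / (Y.shape[0] - lag),
                tau=tau, n_frames_used=Y.shape[0], source="empirical",
            )
            sol = solve_vac(corr)
            est_sub = FunctionSubspace(Bgrid @ sol.V[:, j - 1 : k], ref.mu)
            total[r_idx, t_idx] = projection_distance(est_sub, H)
            estim[r_idx, t_idx] = projection_distance(est_sub, ideal_subs[t_idx])
            calc[r_idx, t_idx] = asymptotic_mse(
                tr, cfg.basis, sol, j, k, basis_values=Y
            ).root_mse
            m_e = min(n_eig, sol.m)
            eigs[r_idx, t_idx, :m_e] = sol.eigenvalues[:m_e]

    return ErrorCurves(
        config=cfg, tau_grid=cfg.tau_grid, approximation=approx, total=total,
        estimation=estim, calculated_rmse=calc, eigenvalues=eigs,
        ideal_eigenvalues=ideal_eigs, kappas=kappas,
    )


def run_ou_trial(trial: int, **overrides) -> ErrorCurves:
    """OU study, trial 1 (n=20, T=1e4) or trial 2 (n=50, T=500)."""
    return run_experiment(ou_trial_config(trial, **overrides))


def run_doublewell(subspace=(1, 3), **overrides) -> ErrorCurves:
    """2D double-well study for subspace (1,2) or (1,3)."""
    return run_experiment(doublewell_config(subspace, **overrides))


def implied_timescale_report(curves: ErrorCurves, indices=(2, 3)) -> pd.DataFrame:
    """Median implied timescales -tau/log(lambda_i) per lag, with a
    flatness metric (relative change over the upper half of the grid).

    Lags where an eigenvalue estimate is outside (0, 1) yield NaN and are
    excluded from the flatness metric.
    """
    taus = curves.tau_grid
    rows = {"tau": taus}
    flatness = {}
    for i in indices:
        lam = curves.eigenvalues[:, :, i - 1]  # (n_rep, n_tau)
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = np.where((lam > 0) & (lam < 1), -taus[None, :] / np.log(lam),
                          np.nan)
        med = np.nanmedian(ts, axis=0)
        rows[f"timescale_{i}"] = med
        upper = med[len(taus) // 2 :]
        upper = upper[np.isfinite(upper)]
        if upper.size >= 2:
            flatness[i] = float(
                (upper.max() - upper.min()) / max(abs(np.median(upper)), 1e-12)
            )
        else:
            flatness[i] = np.nan
    df = pd.DataFrame(rows)
    df.attrs["flatness"] = flatness
    return df
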