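"""Reversible diffusion models and stationary trajectory simulation.

The processes here follow the overdamped Langevin form

    dX = -(1/2) a grad U(X) dt + sigma dW,      a = sigma sigma^T,

whose stationary density is proportional to exp(-U).  Two benchmark
systems are provided: the 1D Ornstein--Uhlenbeck process
dX = -X dt + sqrt(2) dW (U = x^2/2) and a 2D double-well diffusion with
an anisotropic, correlated noise matrix.  Both admit a grid oracle (see
:mod:`vacdyn.oracle`) so that every spectral quantity estimated from a
trajectory can be compared with its exact counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "SdeModel",
    "Trajectory",
    "make_ou1d",
    "make_doublewell2d",
    "simulate",
    "simulate_ensemble",
    "save_trajectory",
    "load_trajectory",
]


@dataclass(frozen=True)
class SdeModel:
    """A reversible diffusion dX = -(1/2) a grad U dt + sigma dW.

    Parameters
    ----------
    dim : int
        State dimension.
    potential : callable
        U(x); accepts arrays of shape (..., dim), returns shape (...).
    grad_potential : callable
        grad U(x); accepts (..., dim), returns (..., dim).
    sigma : ndarray, shape (dim, dim)
        Constant diffusion factor; a = sigma @ sigma.T must be SPD.
    name : str
        Identifier used in trajectory metadata.
    """

    dim: int
    potential: Callable[[np.ndarray], np.ndarray]
    grad_potential: Callable[[np.ndarray], np.ndarray]
    sigma: np.ndarray
    name: str

    @property
    def a(self) -> np.ndarray:
        """Diffusion matrix a = sigma sigma^T."""
        return self.sigma @ self.sigma.T

    def drift(self, x: np.ndarray) -> np.ndarray:
        """Drift -(1/2) a grad U(x), vectorized over leading axes."""
        x = np.asarray(x, dtype=float)
        g = self.grad_potential(x)
        return -0.5 * g @ self.a.T


@dataclass(frozen=True)
class Trajectory:
    """Frames of a stationary time series sampled every `delta` time units."""

    states: np.ndarray  # (frames, dim)
    delta: float
    seed: int
    model_name: str = ""
    burn_in_discarded: float = 0.0

    def __post_init__(self):
        states = np.asarray(self.states, dtype=float)
        if states.ndim == 1:
            states = states[:, None]
        object.__setattr__(self, "states", states)
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if states.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(states)):
            raise ValueError("trajectory contains non-finite states")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def total_time(self) -> float:
        return self.n_frames * self.delta


def make_ou1d() -> SdeModel:
    """The 1D Ornstein--Uhlenbeck process dX = -X dt + sqrt(2) dW.

    U(x) = x^2/2 and sigma = sqrt(2), so the drift is -x and the
    stationary law is the standard normal.  Generator eigenvalues are
    the nonnegative integers with Hermite eigenfunctions.
    """
    return SdeModel(
        dim=1,
        potential=lambda x: 0.5 * np.asarray(x)[..., 0] ** 2,
        grad_potential=lambda x: np.asarray(x, dtype=float),
        sigma=np.array([[np.sqrt(2.0)]]),
        name="ou1d",
    )


def _dw_potential(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    return 4 * x1**4 - 8 * x1**2 + x1 + 0.5 * x2**2


def _dw_grad(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    return np.stack([16 * x1**3 - 16 * x1 + 1.0, x2], axis=-1)


def make_doublewell2d() -> SdeModel:
    """2D double-well diffusion: U = 4x1^4 - 8x1^2 + x1 + x2^2/2.

    sigma = [[2, 0], [-1, 3]] gives a = [[4, -2], [-2, 10]]; the
    metastable hopping along x1 produces one slow relaxation mode well
    separated from the rest of the spectrum.
    """
    return SdeModel(
        dim=2,
        potential=_dw_potential,
        grad_potential=_dw_grad,
        sigma=np.array([[2.0, 0.0], [-1.0, 3.0]]),
        name="doublewell2d",
    )


class IntegrationFailure(RuntimeError):
    """Raised when Euler--Maruyama produces a non-finite state."""


def _em_steps(model, x, dt, n_steps, rng, check_every=1000):
    """Advance an ensemble (n_traj, dim) by n_steps Euler-Maruyama steps."""
    sig = model.sigma
    sqdt = np.sqrt(dt)
    for step in range(n_steps):
        noise = rng.standard_normal(x.shape)
        x = x + model.drift(x) * dt + sqdt * (noise @ sig.T)
        if step % check_every == 0 and not np.all(np.isfinite(x)):
            raise IntegrationFailure(
                f"non-finite state at internal step {step} (dt={dt})"
            )
    if not np.all(np.isfinite(x)):
        raise IntegrationFailure(f"non-finite state after {n_steps} steps (dt={dt})")
    return x


def _initial_ensemble(model, n_traj, rng):
    if model.name == "ou1d":
        # exact stationary sampler: standard normal
        return rng.standard_normal((n_traj, 1))
    if model.dim == 2 and model.name == "doublewell2d":
        # start near each well with stationary x2; burn-in does the rest
        x1 = np.where(rng.random(n_traj) < 0.5, -1.0, 1.0)
        return np.stack([x1 + 0.1 * rng.standard_normal(n_traj),
                         rng.standard_normal(n_traj)], axis=-1)
    return 0.1 * rng.standard_normal((n_traj, model.dim))


def simulate_ensemble(
    model: SdeModel,
    n_traj: int,
    total_time: float,
    delta: float,
    sub_steps: int = 1,
    seed: int = 0,
    burn_in: float = 0.0,
) -> list[Trajectory]:
    """Simulate `n_traj` independent stationary trajectories in lockstep.

    All trajectories advance simultaneously as an (n_traj, dim) ensemble,
    which keeps the per-step cost at a handful of vectorized array
    operations.  Reproducible: the same (seed, parameters) always yields
    bit-identical output.
    """
    if total_time <= 0 or delta <= 0:
        raise ValueError("total_time and delta must be positive")
    if sub_steps < 1:
        raise ValueError("sub_steps must be >= 1")
    rng = np.random.default_rng(seed)
    dt = delta / sub_steps
    x = _initial_ensemble(model, n_traj, rng)

    n_burn = int(round(burn_in / dt))
    if n_burn:
        x = _em_steps(model, x, dt, n_burn, rng)

    n_frames = int(np.floor(total_time / delta))
    out = np.empty((n_frames, n_traj, model.dim))
    for f in range(n_frames):
        x = _em_steps(model, x, dt, sub_steps, rng, check_every=max(sub_steps, 1))
        out[f] = x
    return [
        Trajectory(out[:, i], delta=delta, seed=seed, model_name=model.name,
                   burn_in_discarded=burn_in)
        for i in range(n_traj)
    ]


def simulate(
    model: SdeModel,
    total_time: float,
    delta: float,
    sub_steps: int = 1,
    seed: int = 0,
    burn_in: float = 0.0,
) -> Trajectory:
    """Simulate one stationary trajectory (Euler--Maruyama, step delta/sub_steps)."""
    return simulate_ensemble(
        model, 1, total_time, delta, sub_steps=sub_steps, seed=seed, burn_in=burn_in
    )[0]


# ---------------------------------------------------------------------------
# trajectory I/O: delimited text and an .npz binary container

def save_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory; `.npz` suffix selects the lossless binary form."""
    if str(path).endswith(".npz"):
        np.savez(
            path,
            states=traj.states,
            delta=traj.delta,
            seed=traj.seed,
            model_name=traj.model_name,
            burn_in_discarded=traj.burn_in_discarded,
        )
    else:
        header = (
            f"delta={traj.delta!r} model={traj.model_name} seed={traj.seed} "
            f"burn_in={traj.burn_in_discarded!r}"
        )
        np.savetxt(path, traj.states, header=header)


def load_trajectory(path: str) -> Trajectory:
    if str(path).endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            return Trajectory(
                states=z["states"],
                delta=float(z["delta"]),
                seed=int(z["seed"]),
                model_name=str(z["model_name"]),
                burn_in_discarded=float(z["burn_in_discarded"]),
            )
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
    states = np.loadtxt(path)
    return Trajectory(
        states=states,
        delta=float(meta.get("delta", 1.0)),
        seed=int(meta.get("seed", 0)),
        model_name=meta.get("model", ""),
        burn_in_discarded=float(meta.get("burn_in", 0.0)),
    )
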