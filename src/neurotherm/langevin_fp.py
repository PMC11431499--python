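"""1-D Langevin simulation and gridded Fokker-Planck thermodynamics.

The stochastic dynamics is the overdamped-form Langevin equation

    (1/mu) dz/dt = F(z, t) + sigma * eta(t),

with delta-correlated unit Gaussian noise, <eta(t) eta(t')> = delta(t - t').
The matching Fokker-Planck description is dP/dt = -dJ/dz with the probability
current

    J(z, t) = mu F(z, t) P(z, t) - (1/2)(mu sigma)^2 dP/dz,

and the continuous-state entropy balance

    S_pr = 2/(mu sigma)^2 * integral J^2 / P dz      (>= 0),
    S_fl = 2/(mu sigma^2) * integral J * F dz.

Numerics: fixed-step Euler-Maruyama (weak order 1 is enough for the
distributional quantities computed here and keeps the noise convention
transparent), second-order central differences for d/dz, trapezoid
integrals.  Every trajectory draws its noise from its own counter-based
stream spawned from the user seed, so ensembles are reproducible and
independent of trajectory ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_markov import RateMatrix

logger = logging.getLogger("neurotherm.langevin_fp")

__all__ = [
    "LangevinModel",
    "GridDensity",
    "TrajectoryEnsemble",
    "simulate_sde",
    "fp_current",
    "fp_entropy_rates",
    "discretize_to_rate_matrix",
    "ensemble_to_csv",
    "ensemble_summary",
]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class LangevinModel:
    """mu, sigma and the deterministic generalized force F(z, t)."""

    mu: float
    sigma: float
    force: Callable[[float, float], float]

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def diffusion(self) -> float:
        """D = (mu sigma)^2 / 2, the diffusion coefficient of z."""
        return 0.5 * (self.mu * self.sigma) ** 2


@dataclass(frozen=True)
class GridDensity:
    """Probability density P on a uniform z-grid at one instant."""

    z: np.ndarray
    P: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        p = np.asarray(self.P, dtype=float)
        if z.ndim != 1 or z.shape != p.shape:
            raise ValueError("z and P must be 1-D arrays of equal length")
        dz = np.diff(z)
        # tolerance allows for float cancellation on grids with large offsets
        tol = max(1e-8, 16 * np.finfo(float).eps * np.abs(z).max() / abs(dz[0]))
        if z.size < 2 or not np.allclose(dz, dz[0], rtol=tol, atol=0.0):
            raise ValueError("grid must be uniform")
        if np.any(p < 0):
            raise ValueError("density must be non-negative")
        norm = np.trapezoid(p, z)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 (got {norm!r})")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "P", p)

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """n_traj Euler-Maruyama paths on a shared time grid."""

    times: np.ndarray
    paths: np.ndarray  # shape (n_traj, n_times)
    seed: int
    dt: float

    @property
    def n_traj(self) -> int:
        return self.paths.shape[0]


def _traj_generators(seed: int, n_traj: int) -> list:
    """One independent, named child stream per trajectory."""
    root = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.Philox(s)) for s in root.spawn(n_traj)]


def simulate_sde(
    model: LangevinModel,
    z0: float,
    dt: float,
    t_end: float,
    n_traj: int,
    seed: int,
    record_every: int = 1,
) -> TrajectoryEnsemble:
    """Euler-Maruyama integration of dz = mu F dt + mu sigma dW.

    Identical (seed, dt, n_traj) always reproduce the ensemble bit-for-bit.
    ``record_every`` thins the stored grid without changing the dynamics.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(t_end / dt))
    # relaxation-time sanity check via a local force gradient
    eps = 1e-6 * max(1.0, abs(z0))
    try:
        slope = (model.force(z0 + eps, 0.0) - model.force(z0 - eps, 0.0)) / (2 * eps)
        if slope != 0.0:
            t_relax = 1.0 / (model.mu * abs(slope))
            if dt >= t_relax / 10.0:
                logger.warning(
                    "dt=%g is not small against the local relaxation time %g", dt, t_relax
                )
    except Exception:  # pragma: no cover - force may reject probe points
        pass

    gens = _traj_generators(seed, n_traj)
    noise = np.empty((n_traj, n_steps))
    for i, g in enumerate(gens):
        noise[i] = g.standard_normal(n_steps)
    amp = model.mu * model.sigma * np.sqrt(dt)

    n_rec = n_steps // record_every + 1
    paths = np.empty((n_traj, n_rec))
    paths[:, 0] = z0
    z = np.full(n_traj, float(z0))
    t = 0.0
    k = 1
    force = np.vectorize(model.force) if not _is_vectorized(model.force) else model.force
    for step in range(n_steps):
        z = z + model.mu * np.asarray(force(z, t)) * dt + amp * noise[:, step]
        t += dt
        if (step + 1) % record_every == 0:
            paths[:, k] = z
            k += 1
    times = np.arange(n_rec) * (dt * record_every)
    return TrajectoryEnsemble(times=times, paths=paths, seed=seed, dt=dt)


def _is_vectorized(f: Callable) -> bool:
    try:
        out = f(np.array([0.0, 1.0]), 0.0)
        return np.shape(out) == (2,)
    except Exception:
        return False


def fp_current(density: GridDensity, model: LangevinModel, time: float | None = None) -> np.ndarray:
    """Probability current J = mu F P - (1/2)(mu sigma)^2 dP/dz on the grid."""
    if density.z.size < 5:
        raise ValueError("need at least 5 grid points")
    t = density.time if time is None else time
    f = np.asarray([model.force(zi, t) for zi in density.z], dtype=float)
    dPdz = np.gradient(density.P, density.dz, edge_order=2)
    return model.mu * f * density.P - model.diffusion * dPdz


def fp_entropy_rates(
    density: GridDensity, model: LangevinModel, time: float | None = None
) -> tuple[float, float]:
    """(S_pr, S_fl) evaluated on the grid; requires sigma > 0."""
    if model.sigma == 0:
        raise ValueError("entropy rates are undefined for sigma = 0")
    t = density.time if time is None else time
    j = fp_current(density, model, time=t)
    f = np.asarray([model.force(zi, t) for zi in density.z], dtype=float)
    p = density.P
    integrand_pr = np.where(p > P_FLOOR, j * j / np.where(p > P_FLOOR, p, 1.0), 0.0)
    s_pr = 2.0 / (model.mu * model.sigma) ** 2 * np.trapezoid(integrand_pr, density.z)
    s_fl = 2.0 / (model.mu * model.sigma**2) * np.trapezoid(j * f, density.z)
    return float(s_pr), float(s_fl)


def discretize_to_rate_matrix(
    model: LangevinModel, z_grid: np.ndarray, time: float = 0.0
) -> RateMatrix:
    """Nearest-neighbour birth-death chain consistent with the Fokker-Planck limit.

    Hopping rates between adjacent cells use the exponential (detailed-balance
    preserving) splitting

        w(i -> i+1) = D/dz^2 * exp(+ mu F(z_mid) dz / (2 D)),
        w(i+1 -> i) = D/dz^2 * exp(- mu F(z_mid) dz / (2 D)),

    which reproduces drift mu*F and diffusion D to O(dz^2); the chain's
    entropy production/flow converge to the continuous Eq. values as the
    grid refines.
    """
    z = np.asarray(z_grid, dtype=float)
    dz = z[1] - z[0]
    d = model.diffusion
    n = z.size
    w = np.zeros((n, n))
    for i in range(n - 1):
        zm = 0.5 * (z[i] + z[i + 1])
        drift = model.mu * model.force(zm, time)
        w[i + 1, i] = d / dz**2 * np.exp(drift * dz / (2 * d))
        w[i, i + 1] = d / dz**2 * np.exp(-drift * dz / (2 * d))
    return RateMatrix(tuple(range(n)), w)


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------


def ensemble_to_csv(ens: TrajectoryEnsemble, path) -> None:
    """Long/tidy CSV: traj_id, t, z."""
    import pandas as pd

    n_traj, n_t = ens.paths.shape
    df = pd.DataFrame(
        {
            "traj_id": np.repeat(np.arange(n_traj), n_t),
            "t": np.tile(ens.times, n_traj),
            "z": ens.paths.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def ensemble_summary(ens: TrajectoryEnsemble) -> dict:
    final = ens.paths[:, -1]
    return {
        "seed": ens.seed,
        "dt": ens.dt,
        "n_traj": int(ens.n_traj),
        "t_end": float(ens.times[-1]),
        "final_mean": float(final.mean()),
        "final_var": float(final.var(ddof=1)) if ens.n_traj > 1 else 0.0,
    }


def summary_to_json(ens: TrajectoryEnsemble, path) -> None:
    with open(path, "w") as fh:
        json.dump(ensemble_summary(ens), fh, indent=1)
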