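"""Thermodynamics of a Brownian particle falling in gravity.

A particle of mass ``m`` with friction coefficient ``k`` in a bath at
temperature ``T`` obeys

    m dv/dt = -k v + F(t) + sqrt(2 m k) sigma_v eta(t),   F(t) = m g + F0(t),

with the fluctuation-dissipation relation sigma_v^2 = kB T / m fixing the
noise amplitude.  In the overdamped (small-mass) limit the height x follows
unrestricted Brownian motion with drift, position variance 2 sigma_x^2 gamma t
(sigma_x = sigma_v / gamma, gamma = k/m), and the position entropy balance is
available in closed form:

    S_x(t)      = (1/2) ln(4 pi e sigma_x^2 gamma t),
    dS_x/dt     = 1/(2t),
    S_pr_x(t)   = 1/(2t) + (m g + F0(t))^2 / (gamma k^2 sigma_x^2),
    S_fl_x(t)   = (m g + F0(t))^2 / (gamma k^2 sigma_x^2) = k <v>^2 / (kB T),

so dS_x/dt = S_pr_x - S_fl_x holds identically and, for F0 = 0, S_pr_x decays
to the asymptote m^3 g^2 / (k^3 sigma_x^2).  The mean mechanical-energy
balance and the overdamped first law

    d<E_mech>/dt = -k<v^2> + <v> F0 + k sigma_v^2
                 ~ -kB T S_fl_x + F0 <v>

close the ledger between dissipated heat and external work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .langevin_fp import LangevinModel

__all__ = [
    "KB",
    "ParticleParams",
    "PositionEntropyTerms",
    "sigma_v_fdt",
    "velocity_moments",
    "position_moments",
    "mech_energy_rate",
    "overdamped_energy_rate",
    "position_entropy_terms",
    "first_law_check",
    "velocity_langevin_model",
    "position_langevin_model",
]

KB = 1.380649e-23  # J/K, exact


def sigma_v_fdt(m: float, T: float) -> float:
    """Stationary velocity standard deviation sqrt(kB T / m) in m/s."""
    if m <= 0 or T <= 0:
        raise ValueError("mass and temperature must be positive")
    return math.sqrt(KB * T / m)


@dataclass(frozen=True)
class ParticleParams:
    """Brownian particle in gravity with an optional modulating force F0(t) [N]."""

    m: float  # kg
    k: float  # kg/s
    g: float = 9.81  # m/s^2
    T: float = 300.0  # K
    F0: Optional[Callable[[float], float]] = None  # N; None means F0 == 0

    def __post_init__(self):
        if self.m <= 0 or self.k <= 0 or self.T <= 0:
            raise ValueError("m, k, T must be positive")

    @property
    def gamma(self) -> float:
        return self.k / self.m

    @property
    def sigma_v(self) -> float:
        return sigma_v_fdt(self.m, self.T)

    @property
    def sigma_x(self) -> float:
        return self.sigma_v / self.gamma

    def f0(self, t: float) -> float:
        return 0.0 if self.F0 is None else float(self.F0(t))

    def force(self, t: float) -> float:
        """Total force F(t) = m g + F0(t)."""
        return self.m * self.g + self.f0(t)

    @property
    def _f0_is_trivial(self) -> bool:
        return self.F0 is None


def velocity_moments(params: ParticleParams, v0: float, t: float) -> tuple[float, float]:
    """Mean and variance of v(t) for the underdamped velocity process.

    mean = e^{-gamma t} [v0 + int_0^t e^{gamma t'} F(t')/m dt'],
    var  = sigma_v^2 (1 - e^{-2 gamma t}).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    g = params.gamma
    if params._f0_is_trivial:
        term = (params.m * params.g / params.k) * (1.0 - math.exp(-g * t))
        mean = v0 * math.exp(-g * t) + term
    else:
        integral, _ = quad(lambda s: math.exp(g * s) * params.force(s) / params.m, 0.0, t,
                           limit=200)
        mean = (v0 + integral) * math.exp(-g * t)
    var = params.sigma_v**2 * (1.0 - math.exp(-2.0 * g * t))
    return mean, var


def position_moments(params: ParticleParams, x0: float, t: float) -> tuple[float, float]:
    """Overdamped mean and variance of the height x(t).

    mean = x0 - (1/k) int_0^t F(t') dt'  (v = -dx/dt: the particle falls),
    var  = 2 sigma_x^2 gamma t.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if params._f0_is_trivial:
        integral = params.m * params.g * t
    else:
        integral, _ = quad(params.force, 0.0, t, limit=200)
    mean = x0 - integral / params.k
    var = 2.0 * params.sigma_x**2 * params.gamma * t
    return mean, var


def mech_energy_rate(params: ParticleParams, mean_v: float, mean_v2: float, f0_t: float) -> float:
    """d<E_mech>/dt = -k<v^2> + <v> F0 + k sigma_v^2 (W)."""
    if mean_v2 < mean_v**2 - 1e-12 * max(1.0, mean_v**2):
        raise ValueError("<v^2> cannot be smaller than <v>^2")
    return -params.k * mean_v2 + mean_v * f0_t + params.k * params.sigma_v**2


def overdamped_energy_rate(params: ParticleParams, f0_t: float) -> float:
    """Overdamped limit d<E_mech>/dt ~ -(m g / k)(m g + F0) (W)."""
    return -(params.m * params.g / params.k) * (params.m * params.g + f0_t)


@dataclass(frozen=True)
class PositionEntropyTerms:
    entropy: float  # S_x(t), nats
    rate: float  # dS_x/dt, nats/s
    production: float  # S_pr_x, nats/s
    flow: float  # S_fl_x, nats/s


def position_entropy_terms(params: ParticleParams, t: float, f0_t: float = 0.0) -> PositionEntropyTerms:
    """Closed-form position entropy ledger at time t > 0."""
    if t <= 0:
        raise ValueError("t must be positive")
    g = params.gamma
    sx2 = params.sigma_x**2
    s_x = 0.5 * math.log(4.0 * math.pi * math.e * sx2 * g * t)
    ds = 0.5 / t
    drive = (params.m * params.g + f0_t) ** 2 / (g * params.k**2 * sx2)
    return PositionEntropyTerms(entropy=s_x, rate=ds, production=ds + drive, flow=drive)


def first_law_check(params: ParticleParams, t: float, f0_t: float = 0.0) -> float:
    """|d<E_mech>/dt - (-kB T S_fl_x + F0 <v>)| in W; 0 in the overdamped forms."""
    terms = position_entropy_terms(params, t, f0_t)
    mean_v = (params.m * params.g + f0_t) / params.k
    lhs = overdamped_energy_rate(params, f0_t)
    rhs = -KB * params.T * terms.flow + f0_t * mean_v
    return abs(lhs - rhs)


# ---------------------------------------------------------------------------
# Langevin models for simulation cross-checks
# ---------------------------------------------------------------------------


def velocity_langevin_model(params: ParticleParams) -> LangevinModel:
    """Velocity SDE m dv/dt = -k v + F(t) + sqrt(2 m k) sigma_v eta."""
    m = params.m

    def force(v, t):
        return -params.k * v + params.force(t)

    sigma = math.sqrt(2.0 * m * params.k) * params.sigma_v
    return LangevinModel(mu=1.0 / m, sigma=sigma, force=force)


def position_langevin_model(params: ParticleParams) -> LangevinModel:
    """Overdamped height SDE dx/dt = -F(t)/k - sqrt(2 gamma) sigma_x eta."""

    def force(x, t):
        return -params.force(t)

    sigma = params.k * math.sqrt(2.0 * params.gamma) * params.sigma_x
    return LangevinModel(mu=1.0 / params.k, sigma=sigma, force=force)
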