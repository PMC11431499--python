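"""Noisy linear recurrent network inferring a stochastic stimulus velocity.

A population of N rate neurons with Gaussian tuning curves

    c_i(v) = r_m exp(-(v - u_i)^2 / (2 eps^2))

and mean recurrent weight w_bar obeys, after mean-field reduction, the
population-rate SDE

    dr/dt = -(r - kappa * cbar(v)) / tau_n + sqrt(2 sigma_r^2 / (N tau_n)) eta,

with network enhancement factor kappa = 1/(1 - w_bar tau_n0), effective time
constant tau_n = kappa tau_n0 and noise sigma_r = kappa sigma_r0.  With
preferred velocities u_i ~ Normal(0, alpha^2) and alpha >> eps the population
tuning curve is cbar(v) ~ (r_m eps / alpha) exp(-v^2 / 2 alpha^2), expanded
to (r_m eps / alpha)(1 - v^2 / 2 alpha^2) in the large-alpha regime used by
every closed form below.

The mutual information between the collective rate and the stimulus velocity
is proportional to the doubly filtered autocovariance of v^2; for an
exponential covariance C0 exp(-|t1-t2|/tau_c) it saturates at

    I_inf = N (eps kappa r_m)^2 / (8 alpha^6 sigma_r^2)
            * C0 tau_n^2 tau_c / (tau_n + tau_c),

a grouping verified here by brute-force quadrature of the defining double
integral (see tests).  The conditional entropy production of the tracking
dynamics is evaluated from the Gaussian conditional law (the route through
the continuous-state entropy-production integral, which is unambiguous):

    S(t) = e^{-2t/tau_n} / (tau_n (e^{2t/tau_n} - 1))
           + N (<r(v,t)> - kappa cbar(v(t)))^2 / (tau_n sigma_r^2),

whose long-time limit is the squared deviation of v^2 from its exponentially
filtered history with prefactor N (eps kappa r_m)^2 / (4 alpha^6 sigma_r^2 tau_n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import quad

from .langevin_fp import LangevinModel, TrajectoryEnsemble, simulate_sde

logger = logging.getLogger("neurotherm.neural_inference")

__all__ = [
    "PopulationParams",
    "OUSquaredStimulus",
    "tuning_curve",
    "population_tuning",
    "simulate_population",
    "conditional_mean",
    "sigma_r_sq_t",
    "mutual_info_numeric",
    "mutual_info_stationary",
    "conditional_entropy_production",
    "conditional_entropy_production_longtime",
]


@dataclass(frozen=True)
class PopulationParams:
    """Network parameters; velocities in mm/s, rates in Hz, times in s."""

    N: int
    tau_n0: float  # s
    sigma_r0: float  # Hz
    w_bar: float  # 1/s
    r_m: float  # Hz
    epsilon: float  # mm/s
    alpha: float  # mm/s

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.tau_n0 <= 0 or self.sigma_r0 < 0 or self.epsilon <= 0 or self.alpha <= 0:
            raise ValueError("tau_n0, epsilon, alpha must be positive; sigma_r0 >= 0")
        if self.w_bar < 0 or self.w_bar * self.tau_n0 >= 1.0:
            raise ValueError("need 0 <= w_bar < 1/tau_n0 for a stable network")
        if self.alpha / self.epsilon < 10:
            logger.warning(
                "alpha/epsilon = %.3g is not large; the alpha-series closed forms "
                "lose accuracy",
                self.alpha / self.epsilon,
            )

    @property
    def kappa(self) -> float:
        return 1.0 / (1.0 - self.w_bar * self.tau_n0)

    @property
    def tau_n(self) -> float:
        return self.kappa * self.tau_n0

    @property
    def sigma_r(self) -> float:
        return self.kappa * self.sigma_r0


def tuning_curve(v, u_i: float, r_m: float, epsilon: float):
    """Single-neuron Gaussian tuning curve r_m exp(-(v-u)^2 / 2 eps^2)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    v = np.asarray(v, dtype=float)
    out = r_m * np.exp(-((v - u_i) ** 2) / (2.0 * epsilon**2))
    return float(out) if out.ndim == 0 else out


def population_tuning(v, r_m: float, epsilon: float, alpha: float, order: str = "exact"):
    """Population-average tuning curve for u_i ~ Normal(0, alpha^2), alpha >> eps.

    order="exact":  (r_m eps/alpha) exp(-v^2 / 2 alpha^2)
    order="series": (r_m eps/alpha) (1 - v^2 / 2 alpha^2)   [O(alpha^-2) expansion]
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    v = np.asarray(v, dtype=float)
    amp = r_m * epsilon / alpha
    if order == "exact":
        out = amp * np.exp(-(v**2) / (2.0 * alpha**2))
    elif order == "series":
        out = amp * (1.0 - v**2 / (2.0 * alpha**2))
    else:
        raise ValueError("order must be 'exact' or 'series'")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# stimulus models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OUSquaredStimulus:
    """Gaussian stimulus velocity whose square has exponential autocovariance.

    v(t) is a stationary zero-mean Ornstein-Uhlenbeck process.  For such a
    process cov(v^2(t1), v^2(t2)) = 2 s^4 exp(-2|t1-t2|/tau_v); choosing the
    OU relaxation time tau_v = 2 tau_c and variance s^2 = sqrt(C0/2) gives
    exactly cov(v^2) = C0 exp(-|t1-t2|/tau_c).
    """

    C0: float  # (mm/s)^4
    tau_c: float  # s

    def __post_init__(self):
        if self.C0 < 0 or self.tau_c <= 0:
            raise ValueError("C0 >= 0 and tau_c > 0 required")

    @property
    def ou_tau(self) -> float:
        return 2.0 * self.tau_c

    @property
    def ou_var(self) -> float:
        return math.sqrt(self.C0 / 2.0)

    def v2_covariance(self, lag) -> np.ndarray:
        return self.C0 * np.exp(-np.abs(lag) / self.tau_c)

    def mean_v2(self) -> float:
        return self.ou_var

    def sample_paths(self, times: np.ndarray, n_paths: int, seed: int) -> np.ndarray:
        """Exact stationary OU sampling on an arbitrary increasing grid."""
        times = np.asarray(times, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        s = math.sqrt(self.ou_var)
        v = np.empty((n_paths, times.size))
        v[:, 0] = s * rng.standard_normal(n_paths)
        for k in range(1, times.size):
            rho = math.exp(-(times[k] - times[k - 1]) / self.ou_tau)
            v[:, k] = rho * v[:, k - 1] + s * math.sqrt(1 - rho**2) * rng.standard_normal(n_paths)
        return v


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _as_v_func(v_path: Union[float, Callable[[float], float]]) -> Callable[[float], float]:
    if callable(v_path):
        return v_path
    v_const = float(v_path)
    return lambda t: v_const


def simulate_population(
    params: PopulationParams,
    v_path: Union[float, Callable[[float], float]],
    rbar0: float,
    dt: float,
    t_end: float,
    n_traj: int,
    seed: int,
) -> TrajectoryEnsemble:
    """Euler-Maruyama ensemble of the population rate for a given velocity path.

    Transiently negative rates are not clipped: the Gaussian law used by the
    closed forms is exact for the linear model, and negativity is a transient
    finite-N artifact.  The fraction of negative samples is logged.
    """
    if dt >= params.tau_n / 10:
        logger.warning("dt=%g is not small against tau_n=%g", dt, params.tau_n)
    vf = _as_v_func(v_path)
    kappa = params.kappa

    def drift(r, t):
        c = population_tuning(vf(t), params.r_m, params.epsilon, params.alpha, "exact")
        return -(r - kappa * c) / params.tau_n

    # map to the generic Langevin contract: mu=1, sigma = sqrt(2 sigma_r^2/(N tau_n))
    sigma = math.sqrt(2.0 * params.sigma_r**2 / (params.N * params.tau_n))
    model = LangevinModel(mu=1.0, sigma=sigma, force=drift)
    ens = simulate_sde(model, rbar0, dt, t_end, n_traj, seed)
    neg_frac = float(np.mean(ens.paths < 0))
    if neg_frac > 0:
        logger.info("fraction of transiently negative rate samples: %.3g", neg_frac)
    return ens


def conditional_mean(
    params: PopulationParams,
    v_path: Union[float, Callable[[float], float]],
    rbar0: float,
    t: float,
) -> float:
    """<r(v,t)>: delayed-filter response of the population rate to v(t).

    rbar0 e^{-t/tau} + (eps kappa r_m / alpha)(1 - e^{-t/tau})
        - (eps kappa r_m / (2 tau alpha^3)) e^{-t/tau} int_0^t e^{t'/tau} v^2(t') dt'.
    """
    tau = params.tau_n
    amp = params.epsilon * params.kappa * params.r_m
    base = rbar0 * math.exp(-t / tau) + (amp / params.alpha) * (1.0 - math.exp(-t / tau))
    if t == 0:
        return rbar0
    if not callable(v_path):
        # exponentially filtered v^2 history, (1/tau) int_0^t e^{(t'-t)/tau} v^2 dt'
        filt = float(v_path) ** 2 * (1.0 - math.exp(-t / tau))
    else:
        filt, _ = quad(
            lambda s: math.exp((s - t) / tau) * v_path(s) ** 2 / tau, 0.0, t, limit=400
        )
    return base - amp * filt / (2.0 * params.alpha**3)


def sigma_r_sq_t(params: PopulationParams, t: float) -> float:
    """Conditional variance scale sigma_r^2(t) = sigma_r^2 (1 - e^{-2t/tau_n})."""
    return params.sigma_r**2 * (1.0 - math.exp(-2.0 * t / params.tau_n))


def mutual_info_numeric(
    params: PopulationParams,
    stimulus,
    t: float,
    n_mc: int = 0,
    seed: int = 0,
    n_grid: int = 201,
) -> float:
    """Mutual information at time t from the double-filtered v^2 covariance.

    I = N (eps kappa r_m)^2 / (8 alpha^6 sigma_r^2(t)) *
        e^{-2t/tau} double-int e^{(t1+t2)/tau} cov(v^2(t1), v^2(t2)) dt1 dt2.

    The covariance comes from ``stimulus.v2_covariance`` when available
    (stationary analytic form) and otherwise from ``n_mc`` sampled paths.
    """
    tau = params.tau_n
    tg = np.linspace(0.0, t, n_grid)
    if hasattr(stimulus, "v2_covariance") and n_mc == 0:
        cov = stimulus.v2_covariance(tg[:, None] - tg[None, :])
    else:
        if n_mc <= 1:
            raise ValueError("n_mc paths required for a sampled stimulus")
        v = stimulus.sample_paths(tg, n_mc, seed)
        v2 = v**2
        v2 -= v2.mean(axis=0, keepdims=True)
        cov = v2.T @ v2 / (n_mc - 1)
    kernel = np.exp((tg[:, None] + tg[None, :] - 2.0 * t) / tau)
    integrand = kernel * cov
    inner = np.trapezoid(integrand, tg, axis=1)
    double = float(np.trapezoid(inner, tg))
    s2t = sigma_r_sq_t(params, t)
    amp = params.epsilon * params.kappa * params.r_m
    return params.N * amp**2 / (8.0 * params.alpha**6 * s2t) * double


def mutual_info_stationary(params: PopulationParams, C0: float, tau_c: float) -> float:
    """Stationary-limit mutual information for exponential v^2 covariance."""
    if tau_c < 0:
        raise ValueError("tau_c must be non-negative")
    if tau_c == 0:
        return 0.0
    tau = params.tau_n
    amp = params.epsilon * params.kappa * params.r_m
    return (
        params.N
        * amp**2
        / (8.0 * params.alpha**6 * params.sigma_r**2)
        * C0
        * tau**2
        * tau_c
        / (tau + tau_c)
    )


def conditional_entropy_production(
    params: PopulationParams,
    v_path: Union[float, Callable[[float], float]],
    t: float,
    rbar0: float | None = None,
) -> float:
    """Entropy production rate of the rate dynamics conditioned on v (nats/s).

    Derived by inserting the Gaussian conditional density and the drift of the
    population SDE into the continuous-state entropy-production integral:

        S(t) = e^{-2t/tau} / (tau (e^{2t/tau} - 1))
               + N (<r(v,t)> - kappa cbar_series(v(t)))^2 / (tau sigma_r^2).

    If rbar0 is None the initial rate is taken at its stimulus-free fixed
    point eps kappa r_m / alpha (so only the v-tracking mismatch contributes
    to the second term).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    tau = params.tau_n
    vf = _as_v_func(v_path)
    if rbar0 is None:
        rbar0 = params.epsilon * params.kappa * params.r_m / params.alpha
    m = conditional_mean(params, v_path, rbar0, t)
    target = params.kappa * population_tuning(
        vf(t), params.r_m, params.epsilon, params.alpha, "series"
    )
    e2 = math.exp(-2.0 * t / tau)
    term1 = e2 * e2 / (tau * (1.0 - e2))
    term2 = params.N * (m - target) ** 2 / (tau * params.sigma_r**2)
    return term1 + term2


def conditional_entropy_production_longtime(
    params: PopulationParams,
    v_path: Union[float, Callable[[float], float]],
    t: float,
) -> float:
    """Long-time form: prefactor times (v^2(t) - filtered v^2 history)^2.

    S ~ N (eps kappa r_m)^2 / (4 alpha^6 sigma_r^2 tau_n)
        * [v^2(t) - (e^{-t/tau}/tau) int_0^t e^{t'/tau} v^2(t') dt']^2
    """
    tau = params.tau_n
    vf = _as_v_func(v_path)
    v2_now = vf(t) ** 2
    filt, _ = quad(lambda s: math.exp((s - t) / tau) * vf(s) ** 2 / tau, 0.0, t, limit=400)
    amp = params.epsilon * params.kappa * params.r_m
    pref = params.N * amp**2 / (4.0 * params.alpha**6 * params.sigma_r**2 * tau)
    return pref * (v2_now - filt) ** 2
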