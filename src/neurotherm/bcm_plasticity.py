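"""Stochastic BCM synaptic plasticity: bistability, Kramers dwell times, memory.

The per-synapse stochastic BCM rule with a sliding threshold theta is

    dw_i/dt     = lam f_i r (r - theta) - w_i / tau_w + sqrt(2 sigma_w^2/tau_w) xi_i,
    tau_th dtheta/dt = -theta + beta r^2,

and with a quasi-static threshold (tau_th << tau_w) and quasi-static neural
rate r ~ c(v) + tau_n0 fbar wbar, the population-mean weight obeys

    dwbar/dt = F_w(wbar, c) + sqrt(2 sigma_w^2 / (Ns tau_w)) xibar,
    F_w(wbar, c) = lam fbar [c + tau_n0 fbar wbar]^2
                   * (1 - beta [c + tau_n0 fbar wbar]) - wbar / tau_w.

For c = 0 the drift derives from the quartic core potential

    V0(w) = w^2/(2 tau_w) - (lam fbar^3 tau_n0^2 / 3) w^3
            + (lam fbar^4 tau_n0^3 beta / 4) w^4,

which is bistable iff lam tau_w tau_n0 fbar^2 > 4 beta, with stable fixed
points w_d = 0 and w_u and an unstable point w_m in between.  A transient
stimulus c > 0 tilts the potential by a cubic perturbation DeltaV that lowers
the down-to-up barrier.  Kramers' formula converts barrier heights into dwell
times, reducing the collective weight to a two-state (down/up) memory whose
relaxation is the loss of the learned information: the entropy production
rate during forgetting exactly balances the rate of KL-divergence decay, and
the total entropy produced equals the initially stored information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .core_markov import RateMatrix
from .neural_inference import tuning_curve

logger = logging.getLogger("neurotherm.bcm_plasticity")

__all__ = [
    "TuningSpec",
    "BCMParams",
    "BistabilityReport",
    "TwoStateModel",
    "MemoryInformation",
    "drift_full",
    "population_force",
    "bistability",
    "potential",
    "potential_curvature",
    "kramers_times",
    "two_state_reduce",
    "memory_information",
    "simulate_learning",
    "simulate_first_passage",
]


@dataclass(frozen=True)
class TuningSpec:
    """Input tuning c(v) of the postsynaptic neuron."""

    r_m: float = 10.0  # Hz
    u: float = 10.0  # mm/s, preferred velocity
    epsilon: float = 0.1  # mm/s

    def c(self, v):
        return tuning_curve(v, self.u, self.r_m, self.epsilon)


@dataclass(frozen=True)
class BCMParams:
    """Population synaptic-plasticity parameters (nominal values of the model)."""

    lam: float = 1.3  # plasticity amplitude
    beta: float = 1.2  # sliding-threshold coupling
    f_bar: float = 0.9  # Hz, presynaptic rate
    tau_w: float = 200.0  # s
    tau_theta: float = 10.0  # s
    sigma_w: float = 5.0  # single-synapse weight noise std
    Ns: int = 1000
    tau_n0: float = 0.3  # s
    tuning: TuningSpec = TuningSpec()

    def __post_init__(self):
        if min(self.tau_w, self.tau_theta, self.tau_n0) <= 0 or self.Ns <= 0:
            raise ValueError("time constants and Ns must be positive")
        if self.tau_theta / self.tau_w > 0.2:
            logger.warning(
                "tau_theta/tau_w = %.3g: quasi-static threshold assumption is weak",
                self.tau_theta / self.tau_w,
            )

    @property
    def diffusion(self) -> float:
        """Collective weight diffusion D = sigma_w^2 / (Ns tau_w)."""
        return self.sigma_w**2 / (self.Ns * self.tau_w)


# ---------------------------------------------------------------------------
# drift, force, potential
# ---------------------------------------------------------------------------


def drift_full(w_i: float, theta: float, r: float, params: BCMParams) -> tuple[float, float]:
    """Deterministic parts (dw_i/dt, dtheta/dt) of the two-equation BCM rule."""
    dw = params.lam * params.f_bar * r * (r - theta) - w_i / params.tau_w
    dth = (-theta + params.beta * r**2) / params.tau_theta
    return dw, dth


def population_force(w_bar, c: float, params: BCMParams):
    """Generalized force F_w on the population-mean weight (quasi-static r)."""
    w_bar = np.asarray(w_bar, dtype=float)
    y = c + params.tau_n0 * params.f_bar * w_bar
    out = params.lam * params.f_bar * y**2 * (1.0 - params.beta * y) - w_bar / params.tau_w
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BistabilityReport:
    condition_value: float  # lam tau_w tau_n0 fbar^2
    threshold: float  # 4 beta
    beta_f: float  # 4 beta / condition_value
    bistable: bool
    w_down: float
    w_mid: Optional[float]
    w_up: Optional[float]

    def to_dict(self) -> dict:
        return {
            "condition_value": self.condition_value,
            "threshold": self.threshold,
            "beta_f": self.beta_f,
            "bistable": self.bistable,
            "w_down": self.w_down,
            "w_mid": self.w_mid,
            "w_up": self.w_up,
        }


def bistability(params: BCMParams) -> BistabilityReport:
    """Fixed-point structure of F_w at c=0.

    Bistable iff lam tau_w tau_n0 fbar^2 > 4 beta; then
    w_{m,u} = (1 -/+ sqrt(1 - beta_f)) / (2 beta tau_n0 fbar).
    """
    cond = params.lam * params.tau_w * params.tau_n0 * params.f_bar**2
    thr = 4.0 * params.beta
    beta_f = thr / cond
    if beta_f >= 1.0:
        return BistabilityReport(cond, thr, beta_f, False, 0.0, None, None)
    root = math.sqrt(1.0 - beta_f)
    denom = 2.0 * params.beta * params.tau_n0 * params.f_bar
    return BistabilityReport(
        cond, thr, beta_f, True, 0.0, (1.0 - root) / denom, (1.0 + root) / denom
    )


def potential(w_bar, c: float, params: BCMParams):
    """(V, V0, DeltaV) with V = V0 + DeltaV = -int_0^w F_w(x, c) dx.

    V0     = w^2/(2 tau_w) - (lam fbar^3 tau_n0^2/3) w^3 + (lam fbar^4 tau_n0^3 beta/4) w^4
    DeltaV = -lam fbar c^2 (1-beta c) w - (lam fbar^2 tau_n0 c/2)(2-3 beta c) w^2
             + lam fbar^3 tau_n0^2 beta c w^3
    """
    w = np.asarray(w_bar, dtype=float)
    lam, beta, f, tn0, tw = params.lam, params.beta, params.f_bar, params.tau_n0, params.tau_w
    v0 = w**2 / (2 * tw) - lam * f**3 * tn0**2 / 3 * w**3 + lam * f**4 * tn0**3 * beta / 4 * w**4
    dv = (
        -lam * f * c**2 * (1 - beta * c) * w
        - 0.5 * lam * f**2 * tn0 * c * (2 - 3 * beta * c) * w**2
        + lam * f**3 * tn0**2 * beta * c * w**3
    )
    v = v0 + dv
    if v.ndim == 0:
        return float(v), float(v0), float(dv)
    return v, v0, dv


def potential_curvature(w_bar, c: float, params: BCMParams):
    """Analytic V''(w, c) = -dF_w/dw."""
    w = np.asarray(w_bar, dtype=float)
    lam, beta, f, tn0, tw = params.lam, params.beta, params.f_bar, params.tau_n0, params.tau_w
    y = c + tn0 * f * w
    # dF/dw = lam f [2 y (1 - beta y) - beta y^2] tn0 f - 1/tau_w
    dF = lam * f * tn0 * f * (2 * y * (1 - beta * y) - beta * y**2) - 1.0 / tw
    out = -dF
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Kramers dwell times and the two-state memory
# ---------------------------------------------------------------------------


def _fixed_points_with_input(params: BCMParams, c: float) -> tuple[float, float, float]:
    """Stationary points of V(., c): perturbed (w_d, w_m, w_u) via root polishing."""
    from scipy.optimize import brentq

    rep = bistability(params)
    if not rep.bistable:
        raise ValueError("Kramers analysis requires the bistable regime")
    if c == 0.0:
        return 0.0, rep.w_mid, rep.w_up

    def force(w):
        return population_force(w, c, params)

    # bracket each root around the unperturbed one
    wd = _polish_root(force, -0.5 * rep.w_mid, 0.6 * rep.w_mid, brentq)
    wm = _polish_root(force, 0.4 * rep.w_mid, 0.5 * (rep.w_mid + rep.w_up), brentq)
    wu = _polish_root(force, 0.5 * (rep.w_mid + rep.w_up), 2.0 * rep.w_up, brentq)
    return wd, wm, wu


def _polish_root(f, lo, hi, brentq):
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("stimulus too strong: fixed-point structure changed")
    return brentq(f, lo, hi, xtol=1e-14)


def kramers_times(params: BCMParams, c: float = 0.0) -> tuple[float, float]:
    """Kramers dwell times (T_d, T_u) in the wells of V(., c).

    T_d = 2 pi / sqrt(V''_d |V''_m|) * exp[(Ns tau_w / sigma_w^2)
          ((V0_m - V0_d) + (DV_m - DV_d))],  analogously T_u.
    Logs a validity warning when a barrier is not large against the
    collective diffusion scale.
    """
    wd, wm, wu = _fixed_points_with_input(params, c)
    d = params.diffusion
    vm = potential(wm, c, params)[0]
    vd = potential(wd, c, params)[0]
    vu = potential(wu, c, params)[0]
    cd = potential_curvature(wd, c, params)
    cm = potential_curvature(wm, c, params)
    cu = potential_curvature(wu, c, params)
    if cd <= 0 or cu <= 0 or cm >= 0:
        raise ValueError("degenerate well/barrier curvatures")
    bar_d = vm - vd
    bar_u = vm - vu
    if bar_d < 3 * d or bar_u < 3 * d:
        logger.warning(
            "barrier(s) %.3g/%.3g not large against diffusion %.3g: Kramers "
            "prediction is only indicative",
            bar_d,
            bar_u,
            d,
        )
    def _time(curv, barrier):
        log_t = math.log(2.0 * math.pi / math.sqrt(curv * abs(cm))) + barrier / d
        if log_t > 700.0:  # beyond float range: the state is effectively absorbing
            logger.warning("dwell time exp(%.3g) overflows; returning inf", log_t)
            return math.inf
        return math.exp(log_t)

    return _time(cd, bar_d), _time(cu, bar_u)


@dataclass(frozen=True)
class TwoStateModel:
    """Down/up reduction of the collective weight dynamics.

    Rates with the stimulus on (omega_ud, omega_du) and the baseline (c=0)
    rates; pu_inf and the memory lifetime T_m = 1/omega0 refer to baseline.
    """

    omega_ud: float
    omega_du: float
    omega_ud0: float
    omega_du0: float
    delta: float = 0.0  # initial perturbation pu(0) - pu_inf

    def __post_init__(self):
        for r in (self.omega_ud, self.omega_du, self.omega_ud0, self.omega_du0):
            if r <= 0:
                raise ValueError("two-state rates must be positive")

    @property
    def omega0(self) -> float:
        return self.omega_ud0 + self.omega_du0

    @property
    def pu_inf(self) -> float:
        return self.omega_ud0 / self.omega0

    @property
    def pd_inf(self) -> float:
        return self.omega_du0 / self.omega0

    @property
    def memory_lifetime(self) -> float:
        return 1.0 / self.omega0

    def p_u(self, t, p_u0: Optional[float] = None):
        """Baseline relaxation p_u(t) = (p_u(0) - pu_inf) e^{-omega0 t} + pu_inf."""
        if p_u0 is None:
            p_u0 = self.pu_inf + self.delta
        t = np.asarray(t, dtype=float)
        out = (p_u0 - self.pu_inf) * np.exp(-self.omega0 * t) + self.pu_inf
        return float(out) if out.ndim == 0 else out

    def rate_matrix(self, baseline: bool = True) -> RateMatrix:
        """2-state chain, labels ('down', 'up')."""
        oud = self.omega_ud0 if baseline else self.omega_ud
        odu = self.omega_du0 if baseline else self.omega_du
        return RateMatrix(("down", "up"), np.array([[0.0, odu], [oud, 0.0]]))


def two_state_reduce(params: BCMParams, c: float = 0.0, delta: float = 0.0) -> TwoStateModel:
    """Two-state memory model with rates 1/T_d, 1/T_u from Kramers times."""
    td0, tu0 = kramers_times(params, 0.0)
    if c == 0.0:
        td, tu = td0, tu0
    else:
        td, tu = kramers_times(params, c)
    if not all(map(math.isfinite, (td, tu, td0, tu0))):
        raise ValueError(
            "a Kramers dwell time overflows the float range; the two-state "
            "reduction needs a smaller barrier-to-noise ratio (e.g. fewer "
            "synapses or stronger weight noise)"
        )
    return TwoStateModel(
        omega_ud=1.0 / td, omega_du=1.0 / tu, omega_ud0=1.0 / td0, omega_du0=1.0 / tu0,
        delta=delta,
    )


@dataclass(frozen=True)
class MemoryInformation:
    d_kl: float  # nats
    d_kl_rate: float  # nats/s
    entropy_production: float  # nats/s, = -d_kl_rate
    total_entropy: float  # nats, = D_KL at t=0


def memory_information(two_state: TwoStateModel, t: float) -> MemoryInformation:
    """Information decay ledger of the relaxing two-state memory.

    D_KL(t) = pd(t) ln(pd(t)/pd_inf) + pu(t) ln(pu(t)/pu_inf) with
    pu(t) = pu_inf + Delta e^{-omega0 t}; the entropy production rate of the
    relaxation equals -dD_KL/dt and integrates to D_KL(0).
    """
    delta = two_state.delta
    pu_inf, pd_inf = two_state.pu_inf, two_state.pd_inf
    if not (-pu_inf < delta < pd_inf):
        raise ValueError("delta must keep p_u(0) inside (0, 1)")
    w0 = two_state.omega0
    e = math.exp(-w0 * t)

    def _xlx(p, q):
        return 0.0 if p == 0.0 else p * math.log(p / q)

    pu = pu_inf + delta * e
    pd = pd_inf - delta * e
    d_kl = _xlx(pd, pd_inf) + _xlx(pu, pu_inf)
    if delta == 0.0:
        rate = 0.0
    else:
        rate = -w0 * delta * e * math.log(
            (1.0 + delta * e / pu_inf) / (1.0 - delta * e / pd_inf)
        )
    total = _xlx(pd_inf - delta, pd_inf) + _xlx(pu_inf + delta, pu_inf)
    return MemoryInformation(
        d_kl=d_kl, d_kl_rate=rate, entropy_production=-rate, total_entropy=total
    )


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------


def _velocity_ramp(v0: float, accel: float) -> Callable[[float], float]:
    return lambda t: v0 + accel * t


def simulate_learning(
    params: BCMParams,
    v_path: Union[Callable[[float], float], tuple[float, float]],
    w0: float,
    dt: float,
    t_end: float,
    seed: int,
    n_traj: int = 1,
    record_every: int = 100,
    floor_at_zero: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama ensemble of the collective weight under a moving stimulus.

    ``v_path`` is a callable v(t) or a (v0, acceleration) ramp tuple; the
    stimulus enters the force through the tuning curve c(v(t)) (adiabatic
    neural response).  Returns (times, paths) with paths of shape
    (n_traj, n_recorded).  No reflecting boundary at w=0 unless
    ``floor_at_zero`` is set (display option only).
    """
    if dt >= params.tau_n0:
        logger.warning("dt=%g is not small against tau_n0=%g", dt, params.tau_n0)
    vf = _velocity_ramp(*v_path) if isinstance(v_path, tuple) else v_path
    n_steps = int(round(t_end / dt))
    tgrid = np.arange(n_steps) * dt
    c_path = np.asarray(params.tuning.c(vf(tgrid)), dtype=float)
    if c_path.ndim == 0:
        c_path = np.full(n_steps, float(c_path))

    root = np.random.SeedSequence(seed)
    gens = [np.random.Generator(np.random.Philox(s)) for s in root.spawn(n_traj)]
    amp = math.sqrt(2.0 * params.diffusion * dt)

    lam, beta, f, tn0, tw = params.lam, params.beta, params.f_bar, params.tau_n0, params.tau_w
    w = np.full(n_traj, float(w0))
    n_rec = n_steps // record_every + 1
    paths = np.empty((n_traj, n_rec))
    paths[:, 0] = w
    # pre-draw noise per trajectory stream (reproducible irrespective of n_traj)
    noise = np.empty((n_traj, n_steps))
    for i, g in enumerate(gens):
        noise[i] = g.standard_normal(n_steps)
    k = 1
    for step in range(n_steps):
        y = c_path[step] + tn0 * f * w
        force = lam * f * y * y * (1.0 - beta * y) - w / tw
        w = w + force * dt + amp * noise[:, step]
        if floor_at_zero:
            np.maximum(w, 0.0, out=w)
        if (step + 1) % record_every == 0:
            paths[:, k] = w
            k += 1
    times = np.arange(n_rec) * (dt * record_every)
    return times, paths


def simulate_first_passage(
    params: BCMParams,
    c: float,
    w_start: float,
    w_absorb: float,
    n_traj: int,
    dt: float,
    seed: int,
    t_max: float,
) -> np.ndarray:
    """First-passage times from w_start to w >= w_absorb (NaN if not reached)."""
    root = np.random.SeedSequence(seed)
    gens = [np.random.Generator(np.random.Philox(s)) for s in root.spawn(n_traj)]
    amp = math.sqrt(2.0 * params.diffusion * dt)
    lam, beta, f, tn0, tw = params.lam, params.beta, params.f_bar, params.tau_n0, params.tau_w
    n_steps = int(round(t_max / dt))
    out = np.full(n_traj, np.nan)
    w = np.full(n_traj, float(w_start))
    alive = np.ones(n_traj, dtype=bool)
    chunk = 8192
    step = 0
    while step < n_steps and alive.any():
        block = min(chunk, n_steps - step)
        # every stream is consumed in lock-step so results do not depend on
        # which trajectories have already been absorbed
        noise = np.empty((n_traj, block))
        for i, g in enumerate(gens):
            noise[i] = g.standard_normal(block)
        for b in range(block):
            y = c + tn0 * f * w
            force = lam * f * y * y * (1.0 - beta * y) - w / tw
            w = np.where(alive, w + force * dt + amp * noise[:, b], w)
            step += 1
            hit = alive & (w >= w_absorb)
            if hit.any():
                out[hit] = step * dt
                alive &= ~hit
            if not alive.any():
                break
    return out
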