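"""BCM plasticity: bistability, potentials, Kramers times, two-state memory."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from neurotherm.bcm_plasticity import (
    BCMParams,
    TuningSpec,
    TwoStateModel,
    bistability,
    drift_full,
    kramers_times,
    memory_information,
    population_force,
    potential,
    potential_curvature,
    simulate_first_passage,
    simulate_learning,
    two_state_reduce,
)
from neurotherm.core_markov import evolve_master


@pytest.fixture
def fig_params():
    """Nominal parameter set of the learning demonstration."""
    return BCMParams()  # lam=1.3, beta=1.2, f_bar=0.9, tau_w=200, tau_n0=0.3, ...


@pytest.fixture
def symmetric_params():
    """Quartic with equal-depth, equal-curvature wells: V0 = A w^2 (w - wu)^2."""
    return BCMParams(
        lam=1.0, beta=1.0, f_bar=1.0, tau_w=4.5, sigma_w=0.3, Ns=100, tau_n0=1.0,
        tau_theta=0.2,
    )


class TestDriftFull:
    def test_silent_neuron_gives_pure_decay(self, fig_params):
        dw, _ = drift_full(0.8, 5.0, 0.0, fig_params)
        assert dw == pytest.approx(-0.8 / fig_params.tau_w)

    def test_quasi_static_threshold_recovers_reduced_drift(self, fig_params):
        r, w = 2.0, 0.5
        theta = fig_params.beta * r**2
        dw, dth = drift_full(w, theta, r, fig_params)
        reduced = (
            fig_params.lam * fig_params.f_bar * r**2 * (1 - fig_params.beta * r)
            - w / fig_params.tau_w
        )
        assert dth == 0.0
        assert dw == pytest.approx(reduced, rel=1e-12)

    def test_two_equation_system_tracks_reduced_dynamics(self):
        # deterministic dynamics with tau_theta/tau_w = 0.05 and adiabatic
        # neural rate r = c + tau_n0 fbar w
        # the weight dynamics' local relaxation rate here is ~3/s, so the
        # threshold must be much faster than that, not merely faster than 1/tau_w
        p = BCMParams(lam=1.0, beta=0.3, f_bar=1.0, tau_w=20.0, tau_theta=0.05,
                      sigma_w=0.0, Ns=1, tau_n0=1.0)
        c = 1.2

        def rate(w):
            return c + p.tau_n0 * p.f_bar * w

        def full(t, y):
            w, th = y
            r = rate(w)
            return list(drift_full(w, th, r, p))

        def reduced(t, y):
            return [population_force(y[0], c, p)]

        t_end = 60.0
        y_full = solve_ivp(full, (0, t_end), [0.1, p.beta * rate(0.1) ** 2],
                           dense_output=True, rtol=1e-10, atol=1e-12)
        y_red = solve_ivp(reduced, (0, t_end), [0.1], dense_output=True,
                          rtol=1e-10, atol=1e-12)
        ts = np.linspace(3.0, t_end, 40)  # after the fast weight transient
        w_f = y_full.sol(ts)[0]
        w_r = y_red.sol(ts)[0]
        assert np.max(np.abs(w_f / w_r - 1)) < 0.02


class TestPopulationForce:
    def test_down_state_is_fixed_point(self, fig_params):
        assert population_force(0.0, 0.0, fig_params) == 0.0

    def test_up_state_annihilates_force(self, fig_params):
        rep = bistability(fig_params)
        assert population_force(rep.w_up, 0.0, fig_params) == pytest.approx(0.0, abs=1e-12)
        assert population_force(rep.w_mid, 0.0, fig_params) == pytest.approx(0.0, abs=1e-12)

    def test_force_is_negative_potential_gradient(self, fig_params):
        # 4-point central stencil: exact (to roundoff) for a quartic potential
        h = 1e-3
        for c in (0.0, 0.4):
            for w in np.linspace(0.05, 3.5, 9):
                f = lambda x: potential(x, c, fig_params)[0]
                dv = (f(w - 2 * h) - 8 * f(w - h) + 8 * f(w + h) - f(w + 2 * h)) / (12 * h)
                assert -dv == pytest.approx(population_force(w, c, fig_params), abs=1e-10)


class TestBistability:
    def test_nominal_parameters_are_bistable(self, fig_params):
        rep = bistability(fig_params)
        assert rep.condition_value == pytest.approx(63.18, abs=0.005)
        assert rep.threshold == pytest.approx(4.8)
        assert rep.bistable
        assert rep.w_down == 0.0
        assert 0.0 < rep.w_mid < rep.w_up

    def test_fixed_points_match_root_finder(self, fig_params):
        from scipy.optimize import brentq

        rep = bistability(fig_params)
        f = lambda w: population_force(w, 0.0, fig_params)
        wm = brentq(f, 1e-6, 0.5 * (rep.w_mid + rep.w_up), xtol=1e-15)
        wu = brentq(f, 0.5 * (rep.w_mid + rep.w_up), 10.0, xtol=1e-15)
        assert rep.w_mid == pytest.approx(wm, abs=1e-10)
        assert rep.w_up == pytest.approx(wu, abs=1e-10)

    def test_saddle_node_degeneracy(self):
        # beta_f == 1 exactly: w_mid == w_up (monostable boundary)
        p = BCMParams(lam=1.0, beta=1.0, f_bar=1.0, tau_w=4.0, tau_n0=1.0, tau_theta=0.2)
        rep = bistability(p)
        assert rep.beta_f == pytest.approx(1.0)
        assert not rep.bistable

    def test_continuity_near_saddle_node(self):
        gaps = []
        for tw in (4.5, 4.2, 4.05):
            p = BCMParams(lam=1.0, beta=1.0, f_bar=1.0, tau_w=tw, tau_n0=1.0, tau_theta=0.2)
            rep = bistability(p)
            gaps.append(rep.w_up - rep.w_mid)
        assert gaps[0] > gaps[1] > gaps[2] > 0

    def test_monostable_reports_single_fixed_point(self):
        p = BCMParams(lam=0.05, tau_theta=10.0)
        rep = bistability(p)
        assert not rep.bistable
        assert rep.w_mid is None and rep.w_up is None


class TestPotential:
    def test_zero_at_origin(self, fig_params):
        for c in (0.0, 0.3, 1.0):
            v, v0, dv = potential(0.0, c, fig_params)
            assert v == 0.0 and v0 == 0.0 and dv == 0.0

    def test_weak_stimulus_lowers_the_barrier(self, fig_params):
        rep = bistability(fig_params)
        c = 0.3  # moderate input, below the depression regime beta*c < 1
        _, _, dv_m = potential(rep.w_mid, c, fig_params)
        _, _, dv_d = potential(rep.w_down, c, fig_params)
        assert dv_m - dv_d < 0.0

    def test_quadrature_of_force_reproduces_closed_form(self, fig_params):
        rep = bistability(fig_params)
        for c in (0.0, 0.25):
            for w in np.linspace(0.1, 1.2 * rep.w_up, 7):
                v_quad = -quad(lambda x: population_force(x, c, fig_params), 0.0, w,
                               limit=200)[0]
                assert potential(w, c, fig_params)[0] == pytest.approx(v_quad, abs=1e-10)


class TestKramersTimes:
    def test_symmetric_double_well_has_equal_dwell_times(self, symmetric_params):
        rep = bistability(symmetric_params)
        # V0 = A w^2 (w - wu)^2: both wells have equal depth and curvature
        assert potential(rep.w_up, 0.0, symmetric_params)[0] == pytest.approx(0.0, abs=1e-14)
        assert potential_curvature(0.0, 0.0, symmetric_params) == pytest.approx(
            potential_curvature(rep.w_up, 0.0, symmetric_params), rel=1e-10
        )
        td, tu = kramers_times(symmetric_params, 0.0)
        assert td == pytest.approx(tu, rel=1e-10)

    def test_log_time_scales_linearly_with_synapse_count(self, symmetric_params):
        rep = bistability(symmetric_params)
        barrier = potential(rep.w_mid, 0.0, symmetric_params)[0]
        td1, _ = kramers_times(symmetric_params, 0.0)
        p2 = BCMParams(**{**_as_kwargs(symmetric_params), "Ns": 2 * symmetric_params.Ns})
        td2, _ = kramers_times(p2, 0.0)
        d1 = symmetric_params.diffusion
        assert math.log(td2 / td1) == pytest.approx(barrier / d1, rel=1e-10)

    def test_monostable_parameters_rejected(self):
        p = BCMParams(lam=0.05, tau_theta=10.0)
        with pytest.raises(ValueError):
            kramers_times(p, 0.0)

    def test_first_passage_simulation_agrees_within_factor_two(self):
        # reduced barrier (~4 diffusion units) so escapes are observable
        toy = BCMParams(lam=4.8 / 9.0, beta=1.2, f_bar=1.0, tau_w=10.0, sigma_w=0.5,
                        Ns=100, tau_n0=1.0, tau_theta=0.5)
        rep = bistability(toy)
        td, _ = kramers_times(toy, 0.0)
        fpt = simulate_first_passage(toy, 0.0, 0.0, rep.w_up, n_traj=100, dt=0.02,
                                     seed=1234, t_max=30 * td)
        escaped = fpt[np.isfinite(fpt)]
        assert escaped.size >= 95
        assert abs(math.log(escaped.mean() / td)) < math.log(2.0)


def _as_kwargs(p: BCMParams) -> dict:
    return dict(lam=p.lam, beta=p.beta, f_bar=p.f_bar, tau_w=p.tau_w,
                tau_theta=p.tau_theta, sigma_w=p.sigma_w, Ns=p.Ns, tau_n0=p.tau_n0,
                tuning=p.tuning)


class TestTwoStateMemory:
    def test_reduction_rates_are_inverse_dwell_times(self, symmetric_params):
        td, tu = kramers_times(symmetric_params, 0.0)
        ts = two_state_reduce(symmetric_params, 0.0)
        assert ts.omega_ud == pytest.approx(1.0 / td)
        assert ts.omega_du == pytest.approx(1.0 / tu)
        assert ts.pu_inf == pytest.approx(ts.omega_ud0 / ts.omega0)

    def test_up_transitions_dominate_for_nominal_parameters(self):
        # nominal potential shape at a synapse count where the dwell times
        # stay in float range (at Ns=1000 the up barrier is ~1500 diffusion
        # units and T_u overflows outright)
        p = BCMParams(Ns=20)
        ts = two_state_reduce(p, 0.0)
        assert ts.omega_du < 1e-3 * ts.omega_ud  # asymmetric potential

    def test_nominal_synapse_count_overflows_and_is_reported(self, fig_params):
        td, tu = kramers_times(fig_params, 0.0)
        assert math.isinf(tu)
        with pytest.raises(ValueError):
            two_state_reduce(fig_params, 0.0)

    def test_relaxation_matches_master_equation(self):
        ts = TwoStateModel(omega_ud=0.4, omega_du=0.1, omega_ud0=0.4, omega_du0=0.1,
                           delta=0.15)
        times = np.linspace(0.0, 20.0, 9)
        traj = evolve_master(ts.rate_matrix(), [1 - ts.p_u(0.0), ts.p_u(0.0)], times)
        np.testing.assert_allclose(traj.probs[:, 1], ts.p_u(times), atol=1e-10)

    def test_memory_lifetime_is_relaxation_time(self):
        ts = TwoStateModel(omega_ud=0.4, omega_du=0.1, omega_ud0=0.4, omega_du0=0.1,
                           delta=0.2)
        t = ts.memory_lifetime
        decay = (ts.p_u(t) - ts.pu_inf) / (ts.p_u(0.0) - ts.pu_inf)
        assert decay == pytest.approx(math.exp(-1.0), rel=1e-12)


class TestMemoryInformation:
    @staticmethod
    def make_two_state(pu_inf, omega0, delta):
        return TwoStateModel(
            omega_ud=pu_inf * omega0, omega_du=(1 - pu_inf) * omega0,
            omega_ud0=pu_inf * omega0, omega_du0=(1 - pu_inf) * omega0, delta=delta,
        )

    def test_no_perturbation_no_information(self):
        ts = self.make_two_state(0.3, 1.0, 0.0)
        for t in (0.0, 1.0, 10.0):
            info = memory_information(ts, t)
            assert info.d_kl == 0.0
            assert info.total_entropy == 0.0

    def test_entropy_production_balances_information_loss(self):
        ts = self.make_two_state(0.2, 0.5, 0.3)
        for t in (0.0, 1.0, 5.0):
            info = memory_information(ts, t)
            assert info.entropy_production == -info.d_kl_rate
            assert info.entropy_production >= 0.0

    def test_quadrature_of_loss_rate_equals_initial_divergence(self):
        for pu_inf, delta in [(0.2, 0.3), (0.5, 0.2), (0.7, -0.4)]:
            ts = self.make_two_state(pu_inf, 0.5, delta)
            total, _ = quad(lambda t: memory_information(ts, t).entropy_production,
                            0.0, np.inf, limit=400)
            assert total == pytest.approx(memory_information(ts, 0.0).total_entropy,
                                          abs=1e-8)
            assert memory_information(ts, 0.0).d_kl == pytest.approx(
                memory_information(ts, 0.0).total_entropy, rel=1e-12
            )

    def test_total_entropy_independent_of_memory_lifetime(self):
        ref = None
        for omega0 in (0.05, 0.5, 5.0):  # two decades
            ts = self.make_two_state(0.2, omega0, 0.3)
            tot = memory_information(ts, 0.0).total_entropy
            if ref is None:
                ref = tot
            assert tot == pytest.approx(ref, rel=1e-12)

    def test_small_perturbation_series(self):
        pu_inf = 0.3
        for delta in (1e-3, 1e-4):
            ts = self.make_two_state(pu_inf, 1.0, delta)
            tot = memory_information(ts, 0.0).total_entropy
            series = delta**2 / (2 * pu_inf * (1 - pu_inf))
            assert tot == pytest.approx(series, rel=10 * delta)

    def test_perturbation_out_of_range_rejected(self):
        ts = self.make_two_state(0.2, 1.0, 0.9)  # p_u(0) would exceed 1
        with pytest.raises(ValueError):
            memory_information(ts, 1.0)


class TestSimulateLearning:
    def test_slow_ramp_drives_most_seeds_to_up_state(self, fig_params):
        rep = bistability(fig_params)
        times, paths = simulate_learning(
            fig_params, (7.0, 0.02), w0=0.0, dt=0.01, t_end=2000.0, seed=42, n_traj=10
        )
        final = paths[:, -1]
        assert np.sum(final > rep.w_mid) >= 8
        # persistence: once up, stays up for >> tau_w
        idx_cross = np.argmax(paths > rep.w_mid, axis=1)
        for row, k in zip(paths, idx_cross):
            if row[-1] > rep.w_mid:
                assert times[-1] - times[k] > 3 * fig_params.tau_w

    def test_monostable_plasticity_never_sustains_up_state(self, fig_params):
        weak = BCMParams(lam=0.05, tau_theta=10.0)
        rep = bistability(fig_params)  # reference w_mid of the bistable set
        times, paths = simulate_learning(
            weak, (7.0, 0.02), w0=0.0, dt=0.01, t_end=2000.0, seed=42, n_traj=10
        )
        tail = paths[:, times >= 1000.0]
        assert tail.mean() < rep.w_mid

    def test_reproducible_given_seed(self, fig_params):
        t1, p1 = simulate_learning(fig_params, (7.0, 0.02), 0.0, 0.01, 50.0, seed=3,
                                   n_traj=2)
        t2, p2 = simulate_learning(fig_params, (7.0, 0.02), 0.0, 0.01, 50.0, seed=3,
                                   n_traj=2)
        assert np.array_equal(p1, p2)

    def test_floor_option_keeps_weights_nonnegative(self, fig_params):
        _, paths = simulate_learning(fig_params, (0.0, 0.0), 0.0, 0.01, 50.0, seed=9,
                                     n_traj=2, floor_at_zero=True)
        assert np.all(paths >= 0.0)
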