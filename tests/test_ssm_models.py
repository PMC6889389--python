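import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import leukossm as lk
from leukossm.ssm_models import observe_with_loglik

from helpers import linear_tcm_matrices, substep_lengths


class TestMUpdate:
    def test_no_drug_no_effect(self, tcm_params):
        assert lk.m_update(0.0, 0.0, tcm_params, 0.25) == 0.0

    def test_large_dt_asymptote(self, tcm_params):
        d = 40.0
        target = tcm_params.e_tgn * d / (d + tcm_params.h)
        for m0 in (0.0, 0.3, 2.0):
            assert lk.m_update(m0, d, tcm_params, 1e4) == pytest.approx(target)

    def test_matches_ode_solution(self, tcm_params):
        """The update is the exact solution of the piecewise-linear
        cytotoxicity ODE; check against a numerical integration."""
        p = replace(tcm_params, e_tgn=0.2, h=20.0, k_me=0.5)
        m0, d, dt = 0.1, 50.0, 0.25

        def rhs(t, y):
            return [p.k_me * p.e_tgn * d / (d + p.h) - p.k_me * y[0]]

        sol = solve_ivp(rhs, (0.0, dt), [m0], rtol=1e-12, atol=1e-14)
        assert lk.m_update(m0, d, p, dt) == pytest.approx(sol.y[0, -1],
                                                          rel=1e-9)

    def test_closed_form_identity(self, tcm_params):
        # relative error < 1e-12 against the independently coded closed form
        m0, d, dt = 0.42, 33.0, 0.25
        m_ss = tcm_params.e_tgn * d / (d + tcm_params.h)
        expected = m_ss + (m0 - m_ss) * math.exp(-tcm_params.k_me * dt)
        assert lk.m_update(m0, d, tcm_params, dt) == pytest.approx(
            expected, rel=1e-12)


class TestLUpdate:
    def test_steady_state_drift_zero(self, tcm_params):
        l_star = tcm_params.steady_state_log_leuk()
        out = lk.l_update_mean(l_star, 0.0, tcm_params, 0.25)
        assert out == pytest.approx(l_star, abs=1e-12)

    def test_repeated_application_constant_at_steady_state(self, tcm_params):
        l = tcm_params.steady_state_log_leuk()
        for _ in range(100):
            l = lk.l_update_mean(l, 0.0, tcm_params, 0.25)
        assert l == pytest.approx(tcm_params.steady_state_log_leuk(), abs=1e-9)

    def test_hand_evaluated_drift(self, tcm_params):
        p = replace(tcm_params, k_pl_max=2.0, k_L=1.0, rho=3.0, gamma=1.0)
        l, m, dt = math.log(3.0), 0.05, 0.25
        # drift = 2*3/(3+3) - 0.05 - 1 = -0.05
        assert lk.l_update_mean(l, m, p, dt) == pytest.approx(
            math.log(3.0) + dt * (-0.05), rel=1e-12)

    def test_jacobian_matches_finite_difference(self, tcm_params):
        from leukossm import l_drift_jacobian
        from leukossm.ssm_models import l_drift
        for l in (0.3, 1.0, 1.7):
            eps = 1e-6
            fd = (l_drift(l + eps, 0.0, tcm_params)
                  - l_drift(l - eps, 0.0, tcm_params)) / (2 * eps)
            assert l_drift_jacobian(l, tcm_params) == pytest.approx(fd, rel=1e-6)


class TestOuUpdate:
    def test_zero_mean_preserved(self, crp_params):
        for dt in (0.1, 0.25, 5.0):
            mean, _ = lk.ou_update(0.0, crp_params, dt)
            assert mean == 0.0

    def test_stationary_variance_limit(self, crp_params):
        _, var = lk.ou_update(1.0, crp_params, 1e5)
        assert var == pytest.approx(crp_params.stationary_var_v, rel=1e-10)

    def test_variance_against_euler_monte_carlo(self, crp_params):
        """Exact conditional variance vs brute-force Euler simulation of the
        mean-reverting SDE (1e5 paths, step 1e-3)."""
        p = replace(crp_params, theta_ou=1.0, sigma_ou=0.5)
        dt_total, dt_sim, n = 0.25, 1e-3, 100_000
        rng = np.random.default_rng(42)
        v = np.full(n, 0.7)
        steps = int(round(dt_total / dt_sim))
        for _ in range(steps):
            v += -p.theta_ou * v * dt_sim + p.sigma_ou * math.sqrt(dt_sim) \
                * rng.standard_normal(n)
        mean, var = lk.ou_update(0.7, p, dt_total)
        se_mean = v.std(ddof=1) / math.sqrt(n)
        se_var = v.var(ddof=1) * math.sqrt(2.0 / (n - 1))
        assert abs(v.mean() - mean) < 3 * se_mean + 1e-3   # Euler O(dt) slack
        assert abs(v.var(ddof=1) - var) < 3 * se_var + 1e-3


class TestSigmaLOfV:
    def test_values(self, crp_params):
        assert lk.sigma_L_of_v(0.0, crp_params) == crp_params.sigma_L
        p0 = replace(crp_params, beta_crp=0.0)
        for v in (-2.0, 0.0, 3.0):
            assert lk.sigma_L_of_v(v, p0) == crp_params.sigma_L
        p = replace(crp_params, sigma_L=0.1, beta_crp=0.5)
        assert lk.sigma_L_of_v(2.0, p) == pytest.approx(0.1 * math.e)


class TestInitialBelief:
    def test_tcm_values(self, tcm_params):
        b = lk.initial_belief(tcm_params, math.log(3.0))
        np.testing.assert_allclose(b.mean, [0.0, math.log(3.0)])
        np.testing.assert_allclose(b.cov, np.diag([0.0, 0.5]))

    def test_tcm_crp_adds_stationary_v(self, crp_params):
        b = lk.initial_belief(crp_params, math.log(3.0))
        assert b.mean.size == 3 and b.mean[2] == 0.0
        assert b.cov[2, 2] == pytest.approx(crp_params.stationary_var_v)

    def test_stationary_variance_formula(self, crp_params):
        p = replace(crp_params, theta_ou=0.5, sigma_ou=1.0)
        assert lk.initial_belief(p, 1.0).cov[2, 2] == pytest.approx(1.0)

    def test_missing_first_count_rejected(self, tcm_params):
        with pytest.raises(ValueError):
            lk.initial_belief(tcm_params, math.nan)


def _flat_dose(value=0.0):
    return lambda t: value


class TestTransition:
    def test_steady_state_fixed_point_no_noise(self, tcm_params):
        p = replace(tcm_params, sigma_L=1e-300)
        l_star = p.steady_state_log_leuk()
        b0 = lk.StateBelief(0.0, np.array([0.0, l_star]), np.zeros((2, 2)))
        b1 = lk.transition(b0, p, _flat_dose(0.0), 7.0)
        np.testing.assert_allclose(b1.mean, b0.mean, atol=1e-10)
        np.testing.assert_allclose(b1.cov, 0.0, atol=1e-10)

    def test_non_increasing_time_rejected(self, tcm_params):
        b0 = lk.StateBelief(5.0, np.array([0.0, 1.0]), np.diag([0.0, 0.5]))
        with pytest.raises(ValueError):
            lk.transition(b0, tcm_params, _flat_dose(), 5.0)

    def test_matches_exact_linear_gaussian_prediction(self, tcm_params):
        """With the feedback disabled (k_pl_max ~ 0) the model is linear-
        Gaussian and the EKF prediction must equal the exact one."""
        p = replace(tcm_params, k_pl_max=1e-12)
        b = lk.StateBelief(0.0, np.array([0.2, 1.5]),
                           np.array([[0.01, 0.002], [0.002, 0.3]]))
        t_next = 6.3  # not a multiple of dt: exercises the partial step
        mean, cov = b.mean.copy(), b.cov.copy()
        t = 0.0
        for dt in substep_lengths(0.0, t_next, p.dt):
            F, c, Q = linear_tcm_matrices(p, 30.0, dt)
            mean = F @ mean + c
            cov = F @ cov @ F.T + Q
            t += dt
        out = lk.transition(b, p, _flat_dose(30.0), t_next)
        np.testing.assert_allclose(out.mean, mean, atol=1e-10)
        np.testing.assert_allclose(out.cov, cov, atol=1e-10)

    def test_week_ahead_mean_within_monte_carlo_ci(self, tcm_params):
        """EKF one-week predictive mean of L vs 1e5 simulated trajectories
        of the discretised model."""
        p = tcm_params
        rng = np.random.default_rng(7)
        n = 100_000
        l0 = p.steady_state_log_leuk()
        b0 = lk.StateBelief(0.0, np.array([0.05, l0]),
                            np.diag([0.0, 0.04]))
        d = 35.0
        M = np.full(n, 0.05)
        L = l0 + 0.2 * rng.standard_normal(n)
        rg = p.rho ** p.gamma
        t = 0.0
        for dt in substep_lengths(0.0, 7.0, p.dt):
            drift = p.k_pl_max * rg / (rg + np.exp(p.gamma * L)) - M - p.k_L
            L = L + dt * drift + p.sigma_L * math.sqrt(dt) \
                * rng.standard_normal(n)
            m_ss = p.e_tgn * d / (d + p.h)
            M = (M - m_ss) * math.exp(-p.k_me * dt) + m_ss
            t += dt
        out = lk.transition(b0, p, _flat_dose(d), 7.0)
        se = L.std(ddof=1) / math.sqrt(n)
        assert abs(out.mean[1] - L.mean()) < 3 * se + 2e-3  # linearisation slack
        assert out.mean[0] == pytest.approx(M.mean(), rel=1e-9)

    def test_crp_beta_zero_nests_tcm(self, tcm_params, crp_params):
        """With beta_crp = 0 and the CRP channel ignored, the TCM-CRP
        filtered L-marginals equal TCM's exactly."""
        p3 = replace(crp_params, beta_crp=0.0,
                     **{k: getattr(tcm_params, k) for k in tcm_params.FREE})
        b2 = lk.StateBelief(0.0, np.array([0.1, 1.2]),
                            np.array([[0.01, 0.0], [0.0, 0.4]]))
        b3 = lk.StateBelief(0.0, np.array([0.1, 1.2, 0.5]),
                            np.diag([0.01, 0.4, 1.0]))
        o2 = lk.transition(b2, tcm_params, _flat_dose(25.0), 9.0)
        o3 = lk.transition(b3, p3, _flat_dose(25.0), 9.0)
        np.testing.assert_allclose(o3.mean[:2], o2.mean, atol=1e-12)
        np.testing.assert_allclose(o3.cov[:2, :2], o2.cov, atol=1e-12)


class TestObserve:
    def test_observation_at_mean_with_tight_prior(self, tcm_params):
        b = lk.StateBelief(0.0, np.array([0.0, 1.5]), np.diag([0.0, 1e-10]))
        out = lk.observe(b, lk.ObservationVector(l=1.5), tcm_params)
        np.testing.assert_allclose(out.mean, b.mean, atol=1e-8)

    def test_uninformative_observation_is_noop(self, tcm_params):
        p = replace(tcm_params, sigma_leuk=1e8)
        b = lk.StateBelief(0.0, np.array([0.0, 1.5]), np.diag([0.0, 0.5]))
        out = lk.observe(b, lk.ObservationVector(l=9.9), p)
        np.testing.assert_allclose(out.mean, b.mean, atol=1e-8)
        np.testing.assert_allclose(out.cov, b.cov, atol=1e-8)

    def test_scalar_conjugate_gaussian_formulas(self, tcm_params):
        prior_var, r, y, mu = 0.5, tcm_params.sigma_leuk ** 2, 1.0, 1.4
        b = lk.StateBelief(0.0, np.array([0.0, mu]), np.diag([0.0, prior_var]))
        out, ll = observe_with_loglik(b, lk.ObservationVector(l=y), tcm_params)
        post_var = 1.0 / (1.0 / prior_var + 1.0 / r)
        post_mean = post_var * (mu / prior_var + y / r)
        assert out.mean[1] == pytest.approx(post_mean, rel=1e-12)
        assert out.cov[1, 1] == pytest.approx(post_var, rel=1e-12)
        s = prior_var + r
        assert ll == pytest.approx(
            -0.5 * (math.log(2 * math.pi * s) + (y - mu) ** 2 / s), rel=1e-12)

    def test_crp_observation_requires_v_state(self, tcm_params):
        b = lk.StateBelief(0.0, np.array([0.0, 1.5]), np.diag([0.0, 0.5]))
        with pytest.raises(ValueError):
            lk.observe(b, lk.ObservationVector(v=1.0), tcm_params)


@given(pmm=st.floats(0.0, 0.5), pll=st.floats(0.0, 2.0),
       corr=st.floats(-0.9, 0.9), l_obs=st.floats(-1.0, 3.0),
       gap=st.floats(0.5, 21.0))
@settings(max_examples=40, deadline=None)
def test_transition_observe_preserve_psd(pmm, pll, corr, l_obs, gap):
    """Covariances stay symmetric PSD through predict/update cycles."""
    p = lk.default_tcm_crp_parameters()
    cov = np.diag([pmm, pll, 1.0])
    cov[0, 1] = cov[1, 0] = corr * math.sqrt(pmm * pll)
    b = lk.StateBelief(0.0, np.array([0.1, 1.2, 0.0]), cov)
    b = lk.transition(b, p, _flat_dose(30.0), gap)
    b = lk.observe(b, lk.ObservationVector(l=l_obs, v=0.3), p)
    np.testing.assert_allclose(b.cov, b.cov.T, atol=1e-12)
    assert np.linalg.eigvalsh(b.cov).min() >= -1e-10
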