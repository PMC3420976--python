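"""The looming-function family: identities, closed-form peaks, limits."""

import numpy as np
import pytest
from scipy.optimize import brentq

from loomtau import (
    ApproachStimulus,
    EtaParams,
    XiParams,
    angular_size,
    angular_velocity,
    corrected_m_tau,
    correction_rho,
    distance,
    eta,
    eta_peak_closed_form,
    generate_trace,
    inverse_tau,
    lowpass_filter,
    lp_tau,
    m_tau,
    m_tau_peak_closed_form,
    numeric_peak,
    tau,
    tau_min_distance_ratio,
)
from loomtau.noise import NoiseSpec, noisify_trace


class TestTau:
    def test_arithmetic(self):
        assert tau(0.1, 0.05) == pytest.approx(2.0)

    def test_estimates_remaining_time_small_angles(self, small_angle_stim):
        # R = 0.01, v = 1, t_c = 2: at t = 1 tau is within 1e-4 of t_c - t
        stim = small_angle_stim
        th = angular_size(stim, 1.0)
        thd = angular_velocity(stim, 1.0)
        expected = np.arctan(0.01) * (1 + 1e-4) / 0.01  # closed form by hand
        assert tau(th, thd) == pytest.approx(expected, rel=1e-12)
        assert tau(th, thd) == pytest.approx(1.0, rel=2e-4)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            tau(0.1, 0.0)

    def test_minimum_near_contact(self, stim):
        """tau of a clean trace has its minimum where 2 d arctan(R/d) = R."""
        trace = generate_trace(stim, 0.0, stim.collision_time_tc - stim.dt)
        series = tau(trace.theta, trace.theta_dot)
        d_at_min = distance(stim, trace.times[np.argmin(series)])
        # independent oracle: bisection on the critical equation
        R = stim.half_size_R
        root = brentq(lambda d: 2 * d * np.arctan(R / d) - R, 0.01 * R, R)
        assert abs(d_at_min - root) <= stim.speed_v * stim.dt
        assert root / R == pytest.approx(tau_min_distance_ratio(), rel=1e-10)


class TestMTau:
    def test_arithmetic(self):
        assert m_tau(0.1, 0.05, mu=0.05) == pytest.approx(1.0)

    def test_mu_zero_is_tau(self, clean_trace):
        np.testing.assert_array_equal(
            m_tau(clean_trace.theta, clean_trace.theta_dot, 0.0),
            tau(clean_trace.theta, clean_trace.theta_dot),
        )

    def test_dominated_by_tau(self, clean_trace):
        mt = m_tau(clean_trace.theta, clean_trace.theta_dot, 0.3)
        t = tau(clean_trace.theta, clean_trace.theta_dot)
        assert np.all(mt <= t)

    def test_gain_factorization(self, clean_trace):
        mu = 0.7
        g = clean_trace.theta_dot / (mu + clean_trace.theta_dot)
        np.testing.assert_allclose(
            m_tau(clean_trace.theta, clean_trace.theta_dot, mu),
            tau(clean_trace.theta, clean_trace.theta_dot) * g,
            rtol=1e-14,
        )


class TestMTauPeak:
    def test_closed_form_example(self):
        stim = ApproachStimulus(0.05, 2.0, 3.0)
        pk = m_tau_peak_closed_form(stim, mu=1.0)
        assert np.sqrt(0.2025) == pytest.approx(0.45)
        assert stim.collision_time_tc - pk.t_peak == pytest.approx(0.225, rel=1e-12)

    def test_matches_numeric_argmax_small_angle(self):
        stim = ApproachStimulus(0.01, 2.0, 3.0, dt=5e-4)
        mu = 1.0
        trace = generate_trace(stim, 0.0, stim.collision_time_tc - stim.dt)
        approx_tau = stim.collision_time_tc - trace.times
        series = approx_tau * trace.theta_dot / (mu + trace.theta_dot)
        pk_num = numeric_peak(series, trace.times)
        pk_cf = m_tau_peak_closed_form(stim, mu)
        assert abs(pk_num.t_peak - pk_cf.t_peak) <= stim.dt

    def test_size_effect(self):
        # doubling R advances the peak
        a = m_tau_peak_closed_form(ApproachStimulus(0.05, 2.0, 3.0), 1.0)
        b = m_tau_peak_closed_form(ApproachStimulus(0.10, 2.0, 3.0), 1.0)
        assert b.t_peak < a.t_peak

    def test_velocity_effect(self):
        # doubling v (and hence d0) at fixed t_c delays the peak
        a = m_tau_peak_closed_form(ApproachStimulus(0.05, 2.0, 3.0), 1.0)
        b = m_tau_peak_closed_form(ApproachStimulus(0.05, 4.0, 3.0), 1.0)
        assert b.t_peak > a.t_peak

    def test_mu_monotonicity(self):
        """Larger leakage: the peak moves toward contact and gets lower."""
        stim = ApproachStimulus(0.05, 2.0, 3.0)
        peaks = [m_tau_peak_closed_form(stim, mu) for mu in (0.3, 1.0, 3.0, 10.0)]
        t_peaks = [p.t_peak for p in peaks]
        heights = [p.value_peak for p in peaks]
        assert np.all(np.diff(t_peaks) > 0)
        assert np.all(np.diff(heights) < 0)

    def test_peak_before_onset_flagged(self):
        stim = ApproachStimulus(0.05, 2.0, 0.5)
        pk = m_tau_peak_closed_form(stim, mu=1e-4)
        assert pk.before_onset and pk.t_peak < 0

    def test_slope_tends_to_one_for_large_mu(self):
        """d(t_c - t_hat)/dx -> 1 as mu grows over four decades."""
        x = 0.05
        h = 1e-6
        slopes = []
        for mu in (0.1, 1.0, 10.0, 100.0, 1000.0):
            def lead(xx, mu=mu):
                return np.sqrt(xx**2 + 2 * xx / mu)
            slopes.append((lead(x + h) - lead(x - h)) / (2 * h))
        assert np.all(np.diff(slopes) < 0)  # monotone toward 1
        assert slopes[-1] == pytest.approx(1.0, rel=0.01)


class TestEta:
    def test_alpha_zero_limit(self, clean_trace):
        p = EtaParams(alpha=1e-12, amplitude_C=1.0)
        np.testing.assert_allclose(
            eta(clean_trace.theta, clean_trace.theta_dot, p), clean_trace.theta_dot,
            rtol=1e-9,
        )

    def test_peak_angle_independent_of_speed(self):
        """The eta peak always occurs at angular size 2*arctan(1/alpha)."""
        p = EtaParams(alpha=1.5)
        for v in (0.5, 2.0, 8.0):
            stim = ApproachStimulus(0.05, v, 3.0, dt=1e-4)
            trace = generate_trace(stim, 0.0, stim.collision_time_tc - stim.dt)
            series = eta(trace.theta, trace.theta_dot, p)
            pk = numeric_peak(series, trace.times)
            theta_pk = angular_size(stim, min(pk.t_peak, trace.times[-1]))
            assert theta_pk == pytest.approx(2 * np.arctan(1 / 1.5), rel=1e-3)

    def test_closed_form_peak_example(self):
        # alpha = 2, R = 0.04, v = 1: peak leads contact by 0.08 s
        stim = ApproachStimulus(0.04, 1.0, 3.0, dt=1e-4)
        pk = eta_peak_closed_form(stim, EtaParams(alpha=2.0))
        assert stim.collision_time_tc - pk.t_peak == pytest.approx(0.08, rel=1e-12)
        trace = generate_trace(stim, 0.0, stim.collision_time_tc - stim.dt)
        pk_num = numeric_peak(eta(trace.theta, trace.theta_dot, EtaParams(alpha=2.0)), trace.times)
        assert abs(pk_num.t_peak - pk.t_peak) <= stim.dt

    def test_unit_alpha_peak_at_right_angle(self):
        stim = ApproachStimulus(0.05, 1.0, 3.0)
        pk = eta_peak_closed_form(stim, EtaParams(alpha=1.0))
        assert pk.theta_at_peak == pytest.approx(np.pi / 2, rel=1e-12)
        assert stim.collision_time_tc - pk.t_peak == pytest.approx(0.05, rel=1e-12)

    def test_huge_alpha_flagged(self):
        stim = ApproachStimulus(0.05, 1.0, 3.0)
        pk = eta_peak_closed_form(stim, EtaParams(alpha=1e4))
        assert pk.before_onset


class TestCorrectionRho:
    def test_algebraic_identity(self):
        # rho(eps=0) == tau - m_tau
        rho = correction_rho(0.1, 0.05, mu=0.05, eps=0.0)
        assert rho == pytest.approx(2.0 - 1.0, rel=1e-14)

    def test_identity_on_trace(self, clean_trace):
        mu = 0.4
        rho = correction_rho(clean_trace.theta, clean_trace.theta_dot, mu, eps=0.0)
        diff = tau(clean_trace.theta, clean_trace.theta_dot) - m_tau(
            clean_trace.theta, clean_trace.theta_dot, mu
        )
        np.testing.assert_allclose(rho, diff, rtol=1e-10)
        assert np.all(rho >= 0)

    def test_mu_zero(self, clean_trace):
        assert np.all(correction_rho(clean_trace.theta, clean_trace.theta_dot, 0.0) == 0)

    def test_guard_keeps_finite(self):
        assert np.isfinite(correction_rho(0.1, 0.0, mu=0.5, eps=1e-12))


class TestLowpass:
    def test_zero_memory_is_identity(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_almost_equal(lowpass_filter(x, 0.0), x, decimal=14)

    def test_constant_fixed_point(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, 0.9), x, rtol=1e-12)

    def test_unit_step_geometric(self):
        """Step from init 0: y[k] = 1 - xi^k, checked against a plain loop."""
        xi = 0.8
        x = np.ones(40)
        y = lowpass_filter(x, xi, init=0.0)
        # independent oracle: unroll the recursion in pure Python
        oracle = [0.0]
        for xk in x[1:]:
            acc = xi * oracle[-1] + (1 - xi) * xk
            oracle.append(acc)
        np.testing.assert_allclose(y, oracle, rtol=1e-12)
        np.testing.assert_allclose(y, 1 - xi ** np.arange(40), rtol=1e-10)

    def test_invalid_memory(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.ones(3), 1.0)


class TestCorrectedMTau:
    def test_equals_tau_in_no_filter_limit(self, clean_trace):
        params = XiParams(mu=0.8, w=1.0, xi_theta=0.0, xi_theta_dot=0.0, kappa=0.0, eps=0.0)
        xi = corrected_m_tau(clean_trace, params)
        t = tau(clean_trace.theta, clean_trace.theta_dot)
        np.testing.assert_allclose(xi, t, rtol=1e-12)

    def test_equals_m_tau_for_zero_weight(self, clean_trace):
        params = XiParams(mu=0.8, w=0.0, kappa=0.0)
        np.testing.assert_allclose(
            corrected_m_tau(clean_trace, params),
            m_tau(clean_trace.theta, clean_trace.theta_dot, 0.8),
            rtol=1e-14,
        )

    def test_large_mu_approaches_lp_tau(self, clean_trace):
        mu = 1e3 * clean_trace.theta_dot.max()
        params = XiParams(mu=mu, w=1.0, xi_theta=0.95, xi_theta_dot=0.95, eps=1e-12)
        xi = corrected_m_tau(clean_trace, params)
        lp = lp_tau(clean_trace, 0.95, 0.95)
        rel = np.abs(xi - lp) / lp
        assert np.max(rel) < 2e-3  # O(theta_dot/mu)

    def test_kappa_shifts_output(self, clean_trace):
        base = corrected_m_tau(clean_trace, XiParams(mu=0.5, kappa=0.0, eps=0.0))
        shifted = corrected_m_tau(clean_trace, XiParams(mu=0.5, kappa=0.25, eps=0.0))
        np.testing.assert_allclose(shifted - base, 0.25, rtol=1e-9)


class TestLpTau:
    def test_no_filter_is_tau(self, clean_trace):
        np.testing.assert_allclose(
            lp_tau(clean_trace, 0.0, 0.0),
            tau(clean_trace.theta, clean_trace.theta_dot),
            rtol=1e-14,
        )

    def test_noise_suppression(self, stim):
        """Filtered tau fluctuates less than raw tau on noisy traces."""
        clean = generate_trace(stim, 0.5, 2.5)
        var_tau, var_lp = [], []
        for trial in range(100):
            noisy = noisify_trace(clean, NoiseSpec(0.05, 0.05, seed=7), (trial,))
            var_tau.append(np.var(tau(noisy.theta, noisy.theta_dot)[500:1500]))
            var_lp.append(np.var(lp_tau(noisy, 0.99, 0.99)[500:1500]))
        assert np.mean(var_lp) < np.mean(var_tau)

    def test_filter_lag_raises_estimate(self, stim):
        clean = generate_trace(stim, 0.5, 2.5)
        t = tau(clean.theta, clean.theta_dot)
        lp = lp_tau(clean, 0.9, 0.9)
        # while tau shrinks, the lagging filtered version stays above it
        assert np.all(lp[50:] >= t[50:] - 1e-12)


class TestInverseTau:
    def test_arithmetic(self):
        assert inverse_tau(0.2, 0.1) == pytest.approx(0.5)

    def test_peak_coincides_with_tau_minimum(self, stim):
        trace = generate_trace(stim, 0.0, stim.collision_time_tc - stim.dt)
        inv = inverse_tau(trace.theta, trace.theta_dot)
        t = tau(trace.theta, trace.theta_dot)
        assert abs(trace.times[np.argmax(inv)] - trace.times[np.argmin(t)]) <= stim.dt

    def test_peak_linear_in_x_ratio(self):
        """Peak lead time regresses on R/v with slope = the tau-min root."""
        leads, xs = [], []
        for R, v in [(0.02, 1.0), (0.04, 1.0), (0.03, 0.5), (0.05, 2.0), (0.08, 1.6)]:
            stim = ApproachStimulus(R, v, 2.0, dt=1e-4)
            trace = generate_trace(stim, 0.0, stim.collision_time_tc - stim.dt)
            pk = numeric_peak(inverse_tau(trace.theta, trace.theta_dot), trace.times)
            leads.append(stim.collision_time_tc - pk.t_peak)
            xs.append(R / v)
        slope = np.polyfit(xs, leads, 1)[0]
        assert slope == pytest.approx(tau_min_distance_ratio(), abs=1e-3)


class TestNumericPeak:
    def test_parabola_vertex_recovered(self):
        t = np.arange(0, 1, 0.01)
        vertex = 0.5037  # between grid points
        y = -(t - vertex) ** 2
        pk = numeric_peak(y, t)
        assert abs(pk.t_peak - vertex) < 0.1 * 0.01
        assert not pk.at_boundary

    def test_monotone_series_flagged(self):
        t = np.arange(5.0)
        pk = numeric_peak(t * 2, t)
        assert pk.at_boundary and pk.t_peak == 4.0

    def test_tie_breaks_earliest(self):
        y = np.array([0.0, 1.0, 0.5, 1.0, 0.0])
        pk = numeric_peak(y, np.arange(5.0))
        assert pk.t_peak == pytest.approx(1.0)

    def test_degenerate_flagged(self):
        pk = numeric_peak(np.ones(5), np.arange(5.0))
        assert pk.degenerate
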