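"""Efficiency metrics: peak response, critical compression, firing time,
charge-to-fire and the two pulse counts."""

import math

import numpy as np
import pytest
from scipy import integrate

import volley as V
from volley import analytic
from volley.metrics import (
    SweepResult,
    charge_to_fire,
    critical_epsilon,
    firing_time,
    firing_window,
    peak_response,
    pulses_to_threshold,
    pulses_until_fire,
    sweep_delta,
    sweep_epsilon,
    time_ratio,
)
from volley.stimuli import AlphaPulse, DeltaTrain, SynapticTrain


def lif_pulse_response_exact(r, eps, tau, t):
    """Closed-form reset-free LIF response to I_eps (variation of constants)."""
    a = 1.0 / eps - 1.0 / tau
    t = np.asarray(t, float)
    return (r / eps**2) * np.exp(-t / tau) * (1.0 - (1.0 + a * t) * np.exp(-a * t)) / a**2


class TestPeakResponse:
    def test_lif_matches_closed_form_oracle(self, lif10):
        t = np.linspace(0.0, 60.0, 60001)
        expected = lif_pulse_response_exact(1.25, 1.0, 10.0, t).max()
        assert peak_response(lif10, AlphaPulse(1.25, 1.0)) == pytest.approx(expected, rel=1e-6)

    def test_lif_limits(self, lif10):
        """M_eps -> q as eps -> 0 and M_eps -> 0 as eps -> infinity."""
        assert peak_response(lif10, AlphaPulse(1.25, 1e-3)) == pytest.approx(1.25, rel=2e-3)
        assert peak_response(lif10, AlphaPulse(1.25, 1e3)) < 0.01

    def test_theta_infinite_flag_above_one(self, theta_half):
        assert peak_response(theta_half, AlphaPulse(1.25, 0.05)) == math.inf

    def test_theta_subcritical_sup(self, theta_half):
        m = peak_response(theta_half, AlphaPulse(1.25, 1.0))
        assert 0.0 < m < 1.0


class TestCriticalEpsilon:
    def test_subunit_charge_has_no_critical_epsilon(self, lif10, theta_half):
        for model in (lif10, theta_half):
            with pytest.raises(ValueError, match="no critical epsilon"):
                critical_epsilon(model, AlphaPulse(0.9, 1.0))

    def test_peak_is_one_at_the_edge(self, lif10):
        eps0 = critical_epsilon(lif10, AlphaPulse(1.25, 1.0))
        assert peak_response(lif10, AlphaPulse(1.25, eps0)) == pytest.approx(1.0, abs=1e-3)

    def test_dichotomy_grid_scan(self, lif10, theta_half):
        """Spike iff eps <= eps0: scan a grid on both sides of the located edge."""
        for model in (lif10, theta_half):
            eps0 = critical_epsilon(model, AlphaPulse(1.25, 1.0))
            for f in (0.3, 0.7, 0.99):
                assert math.isfinite(firing_time(model, AlphaPulse(1.25, f * eps0)))
            for f in (1.01, 1.5, 4.0):
                assert firing_time(model, AlphaPulse(1.25, f * eps0)) == math.inf

    def test_stronger_pulse_has_larger_window(self, lif10):
        e_weak = critical_epsilon(lif10, AlphaPulse(1.25, 1.0))
        e_strong = critical_epsilon(lif10, AlphaPulse(1.5, 1.0))
        assert e_strong > e_weak


class TestFiringTime:
    def test_lif_vanishes_in_delta_limit(self, lif10):
        assert firing_time(lif10, AlphaPulse(2.0, 1e-4)) < 1e-3

    def test_theta_delta_limit_is_blowup_time(self, theta_half):
        """As eps -> 0 the theta firing time approaches the time to run from
        v = q to infinity: tau*ln(q/(q-1))."""
        T = firing_time(theta_half, AlphaPulse(4.0, 1e-4))
        assert T == pytest.approx(analytic.theta_blowup_time(0.5, 4.0), abs=1e-3)

    def test_theta_diverges_at_critical_epsilon(self, theta_half):
        eps0 = critical_epsilon(theta_half, AlphaPulse(4.0, 1.0))
        times = [firing_time(theta_half, AlphaPulse(4.0, f * eps0)) for f in (0.9, 0.99, 0.9999)]
        assert times[0] < times[1] < times[2]

    def test_constant_drive_spike_matches_closed_form(self, lif10):
        # simulate_lif route, accessed through the sweep-level helper
        from volley.stimuli import ConstantDrive

        tr = V.simulate_lif(lif10, ConstantDrive(0.2), t_end=30.0)
        assert tr.spike_times[0] == pytest.approx(analytic.lif_constant_drive_time(10.0, 5.0), abs=5e-5)


class TestTimeRatioAndCharge:
    def test_lif_ratio_and_charge_strictly_increase(self, lif10):
        eps0 = critical_epsilon(lif10, AlphaPulse(2.0, 1.0))
        grid = np.array([0.05, 0.2, 0.5, 0.8, 0.95]) * eps0
        R = [time_ratio(lif10, AlphaPulse(2.0, e)) for e in grid]
        Q = [charge_to_fire(lif10, AlphaPulse(2.0, e)) for e in grid]
        assert all(a < b for a, b in zip(R, R[1:]))
        assert all(a < b for a, b in zip(Q, Q[1:]))

    def test_theta_ratio_diverges_at_both_ends(self, theta_half):
        eps0 = critical_epsilon(theta_half, AlphaPulse(4.0, 1.0))
        r_small = time_ratio(theta_half, AlphaPulse(4.0, 1e-3))
        r_mid = time_ratio(theta_half, AlphaPulse(4.0, 0.5))
        r_edge = time_ratio(theta_half, AlphaPulse(4.0, 0.9999 * eps0))
        assert r_small > 10.0 * r_mid
        assert r_edge > r_mid
        # closer to the edge, larger still
        assert r_edge > time_ratio(theta_half, AlphaPulse(4.0, 0.99 * eps0))

    def test_charge_equals_direct_quadrature_of_scaled_pulse(self, lif10, theta_half):
        """Q_hat computed from the unscaled pulse over [0, R_hat] equals the
        integral of I_eps over [0, T_hat] (change of variables)."""
        for model, r, eps in ((lif10, 2.0, 1.0), (theta_half, 4.0, 0.3)):
            pulse = AlphaPulse(r, eps)
            T = firing_time(model, pulse)
            direct, _ = integrate.quad(pulse.value, 0.0, T, limit=200)
            assert charge_to_fire(model, pulse) == pytest.approx(direct, rel=1e-6)

    def test_charge_near_q_when_ratio_large(self, wb):
        """With R_hat >> 1 the pulse is over long before firing, so the charge
        to fire is essentially the whole pulse charge q."""
        pulse = AlphaPulse(7.0, 0.3)
        assert time_ratio(wb, pulse) > 20.0
        assert charge_to_fire(wb, pulse) == pytest.approx(7.0, rel=1e-2)

    def test_theta_and_wb_charge_non_monotone(self, theta_half, wb):
        qs_theta = [charge_to_fire(theta_half, AlphaPulse(4.0, e)) for e in (1e-3, 0.5, 2.1)]
        assert qs_theta[0] > qs_theta[1] < qs_theta[2]
        qs_wb = [charge_to_fire(wb, AlphaPulse(20.0, e)) for e in (0.05, 8.0, 15.0)]
        assert qs_wb[0] > qs_wb[1] < qs_wb[2]

    def test_no_spike_is_an_error(self, lif10):
        with pytest.raises(ValueError, match="spike"):
            charge_to_fire(lif10, AlphaPulse(0.9, 1.0))


class TestScalingIdentity:
    def test_lif_compression_equals_tau_rescaling(self):
        """v_eps(t, tau) = v(t/eps, tau/eps): the compressed-pulse response is
        the uncompressed response of a proportionally leakier neuron."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            tau = rng.uniform(2.0, 20.0)
            eps = rng.uniform(0.2, 3.0)
            r = rng.uniform(0.5, 2.0)
            dt = 0.002
            tr_lhs = V.simulate_lif(V.LIFParams(tau), AlphaPulse(r, eps), t_end=10.0 * eps, dt=dt * eps, reset=False)
            tr_rhs = V.simulate_lif(V.LIFParams(tau / eps), AlphaPulse(r, 1.0), t_end=10.0, dt=dt, reset=False)
            assert np.allclose(tr_lhs.v, tr_rhs.v, atol=1e-9)


class TestPulseCounts:
    @pytest.mark.parametrize("w,delta", [(0.3, 1.0), (0.12, 0.5), (0.7, 5.0), (0.05, 0.2)])
    def test_delta_train_count_matches_geometric_oracle(self, lif10, w, delta):
        pred = analytic.delta_train_predict(10.0, w, delta)
        assert pulses_to_threshold(lif10, DeltaTrain(w, delta)) == pred.n_pulses

    def test_too_weak_train_flags_infinity(self, lif10):
        # w <= 1 - e^{-Delta/tau}: threshold never reached
        assert pulses_to_threshold(lif10, DeltaTrain(0.05, 8.0)) == math.inf
        assert pulses_until_fire(lif10, SynapticTrain(0.005, 4.0)) == math.inf

    def test_wb_synaptic_count_increases_with_delta(self, wb):
        n1 = pulses_to_threshold(wb, SynapticTrain(1e-3, 0.5))
        n2 = pulses_to_threshold(wb, SynapticTrain(1e-3, 1.0))
        assert n1 < n2

    def test_fire_count_at_least_threshold_count(self, wb, lif10):
        """M_Delta >= N_Delta: firing happens at or after threshold crossing."""
        for model, train in ((wb, SynapticTrain(0.005, 1.0)), (lif10, SynapticTrain(0.005, 0.25))):
            assert pulses_until_fire(model, train) >= pulses_to_threshold(model, train)

    def test_fire_count_non_monotone_for_lif(self, lif10):
        m = [pulses_until_fire(lif10, SynapticTrain(0.005, d)) for d in (0.05, 0.25, 0.5)]
        assert m[0] > m[1] < m[2]


class TestHoveringNearCriticalCompression:
    def test_time_near_threshold_grows_toward_eps0(self, theta_half):
        """Just below eps0 the trajectory lingers near the repelling level
        v = 1 before resolving; the linger time grows as eps -> eps0."""
        eps0 = critical_epsilon(theta_half, AlphaPulse(1.25, 1.0))

        def hover(eps):
            T = firing_time(theta_half, AlphaPulse(1.25, eps))
            t_end = 1.2 * T
            dt = min(0.01, eps / 50.0)
            tr = V.simulate_theta(theta_half, AlphaPulse(1.25, eps), t_end, dt, v0=0.0)
            v = tr["v"]
            return float(np.sum(np.abs(v - 1.0) < 0.05)) * dt

        h = [hover(eps0 * (1.0 - f)) for f in (1e-2, 1e-3, 1e-4)]
        assert h[0] < h[1] < h[2]


class TestSweepsAndWindow:
    def test_sweep_m_eps_monotone_and_summary(self, lif10):
        grid = np.geomspace(1e-2, 30.0, 12)
        res = sweep_epsilon(lif10, 1.25, grid, "m_eps")
        s = res.summary()
        assert s["monotone_decreasing"] and not s["monotone_increasing"]
        assert res.metric_values[0] == pytest.approx(1.25, rel=0.05)

    def test_sweep_result_validation(self, lif10):
        with pytest.raises(ValueError):
            SweepResult("epsilon", [1.0, 0.5], "m_eps", [1.0, 2.0], lif10)
        with pytest.raises(ValueError):
            SweepResult("epsilon", [1.0, 2.0], "m_eps", [1.0], lif10)

    def test_sweep_csv_roundtrip(self, lif10, tmp_path):
        import pandas as pd

        res = sweep_delta(lif10, [0.5, 1.0], "n_delta", w=0.3)
        p = tmp_path / "sweep.csv"
        res.to_csv(p)
        df = pd.read_csv(p)
        assert list(df.columns)[:2] == ["delta", "n_delta"]
        assert np.allclose(df.n_delta.to_numpy(), res.metric_values)

    def test_wb_firing_window_upper_edge(self, wb):
        lo, hi = firing_window(wb, 7.0, eps_lo=0.05, eps_hi=5.0, n_scan=15)
        assert 0.5 < hi < 1.0  # beyond ~0.7 the stretched pulse cannot fire
        assert math.isfinite(firing_time(wb, AlphaPulse(7.0, 0.9 * hi)))
        assert firing_time(wb, AlphaPulse(7.0, 1.2 * hi)) == math.inf
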