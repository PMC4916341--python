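"""Single-neuron integrators against closed forms and basic physiology."""

import math

import numpy as np
import pytest

import volley as V
from volley import analytic
from volley.models import IntegrationError, model_kind, simulate_lif, simulate_theta, theta_to_v, v_to_theta
from volley.stimuli import AlphaPulse, ConstantDrive, DeltaTrain, SynapticTrain


class TestLIF:
    def test_zero_drive_equilibrium(self, lif10):
        tr = simulate_lif(lif10, None, t_end=20.0)
        assert np.all(tr.v == 0.0)
        assert tr.spike_times.size == 0

    @pytest.mark.parametrize("delta", [5.0, 1.0])
    def test_constant_drive_firing_time_matches_closed_form(self, lif10, delta):
        """Under constant drive 1/Delta the first spike lands at
        tau*ln((tau/Delta)/(tau/Delta - 1))."""
        tr = simulate_lif(lif10, ConstantDrive(1.0 / delta), t_end=30.0)
        expected = analytic.lif_constant_drive_time(10.0, delta)
        assert tr.spike_times[0] == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("delta", [10.0, 12.0])
    def test_no_spike_at_or_above_tau(self, lif10, delta):
        """An action potential occurs iff Delta < tau: at Delta >= tau the
        drive saturates v below threshold for any horizon."""
        tr = simulate_lif(lif10, ConstantDrive(1.0 / delta), t_end=500.0)
        assert tr.spike_times.size == 0
        assert tr.v.max() < 1.0

    def test_single_jump_then_exponential_decay(self, lif10):
        tr = simulate_lif(lif10, DeltaTrain(w=0.5, delta=4.0, n_pulses=1), t_end=24.0)
        t = tr.times
        expected = np.where(t >= 4.0, 0.5 * np.exp(-(t - 4.0) / 10.0), 0.0)
        assert np.allclose(tr.v, expected, atol=1e-9)

    def test_jump_across_threshold_spikes_and_resets(self, lif10):
        tr = simulate_lif(lif10, DeltaTrain(w=1.2, delta=2.0, n_pulses=1), t_end=5.0)
        assert tr.spike_times.size == 1
        assert tr.spike_times[0] == pytest.approx(2.0)
        assert tr.v[-1] == 0.0

    def test_subthreshold_samples_below_one_with_reset(self, lif10):
        tr = simulate_lif(lif10, ConstantDrive(0.5), t_end=50.0)
        assert tr.spike_times.size >= 10
        assert np.all(tr.v < 1.0)

    def test_comparison_principle(self):
        """Leakier neurons stay lower: tau1 < tau2 implies v(t,tau1) <= v(t,tau2)
        for the same nonnegative drive, strictly where v(t,tau2) > 0."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            tau1, tau2 = sorted(rng.uniform(0.5, 20.0, 2))
            if tau2 - tau1 < 0.1:
                tau2 = tau1 + 0.5
            pulse = AlphaPulse(r=rng.uniform(0.5, 3.0), epsilon=rng.uniform(0.2, 3.0))
            tr1 = simulate_lif(V.LIFParams(tau1), pulse, t_end=30.0, reset=False)
            tr2 = simulate_lif(V.LIFParams(tau2), pulse, t_end=30.0, reset=False)
            assert np.all(tr1.v <= tr2.v + 1e-12)
            grown = tr2.v > 1e-4
            grown[0] = False
            assert np.all(tr1.v[grown] < tr2.v[grown])

    def test_dt_halving_moves_spike_time_negligibly(self, lif10):
        t1 = simulate_lif(lif10, ConstantDrive(0.2), 20.0, dt=0.01).spike_times[0]
        t2 = simulate_lif(lif10, ConstantDrive(0.2), 20.0, dt=0.005).spike_times[0]
        assert abs(t1 - t2) < 1e-5


class TestTheta:
    def test_fixed_point_is_stationary(self, theta_half):
        tr = simulate_theta(theta_half, None, t_end=20.0, v0=0.0)
        assert np.allclose(tr["v"], 0.0, atol=1e-12)
        assert not tr.blew_up

    def test_suprathreshold_constant_drive_fires_periodically(self, theta_half):
        # I > 1/(4 tau) = 0.5: fixed points annihilated, periodic firing
        tr = simulate_theta(theta_half, ConstantDrive(0.8), t_end=50.0)
        assert tr.spike_times.size >= 3
        isi = np.diff(tr.spike_times)
        assert np.allclose(isi, isi.mean(), rtol=1e-3)

    def test_subthreshold_drive_never_fires(self, theta_half):
        tr = simulate_theta(theta_half, ConstantDrive(0.4), t_end=200.0)
        assert tr.spike_times.size == 0

    def test_blowup_time_from_suprathreshold_start(self, theta_half):
        """From v = q > 1 with zero drive the voltage reaches infinity at
        t = tau*ln(q/(q-1)) (separation of variables)."""
        q = 4.0
        tr = simulate_theta(theta_half, None, t_end=2.0, dt=1e-4, v0=q)
        assert tr.blew_up
        assert tr.spike_times[0] == pytest.approx(analytic.theta_blowup_time(0.5, q), abs=1e-3)

    def test_jump_mid_run_equivalent_to_initial_condition(self, theta_half):
        """A delta kick to v = 4 at t = 1 reproduces the closed-form blow-up
        delayed by the kick time."""
        tr = simulate_theta(theta_half, DeltaTrain(w=4.0, delta=1.0, n_pulses=1), t_end=3.0, dt=1e-4)
        expected = 1.0 + analytic.theta_blowup_time(0.5, 4.0)
        assert tr.spike_times[0] == pytest.approx(expected, abs=1e-3)

    def test_voltage_stays_nonnegative_under_positive_pulses(self, theta_half):
        for eps in (0.05, 0.5, 2.0):
            tr = simulate_theta(theta_half, AlphaPulse(0.9, eps), t_end=30.0, v0=0.0)
            assert tr["theta"].min() >= v_to_theta(0.0) - 1e-9

    def test_wrapped_phase_range(self, theta_half):
        tr = simulate_theta(theta_half, ConstantDrive(0.8), t_end=20.0)
        th = tr["theta"]
        assert th.min() > -math.pi - 1e-12 and th.max() <= math.pi + 1e-12

    def test_coordinate_maps_inverse(self):
        v = np.array([-3.0, 0.0, 0.25, 0.5, 1.0, 4.0])
        assert np.allclose(theta_to_v(v_to_theta(v)), v, rtol=1e-12)


class TestThetaFixedPoints:
    def test_zero_drive(self, theta_half):
        assert V.theta_fixed_points(theta_half, 0.0) == (0.0, 1.0)

    def test_saddle_node_point(self, theta_half):
        vm, vp = V.theta_fixed_points(theta_half, 0.5)  # tau*I = 1/4
        assert vm == pytest.approx(0.5) and vp == pytest.approx(0.5)

    def test_generic_pair_are_roots(self, theta_half):
        vm, vp = V.theta_fixed_points(theta_half, 0.3)
        assert vm == pytest.approx(0.5 - math.sqrt(0.25 - 0.15))
        assert vp == pytest.approx(0.5 + math.sqrt(0.25 - 0.15))
        for v in (vm, vp):
            assert -v * (1 - v) / 0.5 + 0.3 == pytest.approx(0.0, abs=1e-12)

    def test_beyond_bifurcation(self, theta_half):
        assert V.theta_fixed_points(theta_half, 0.6) is None


class TestHH:
    def test_resting_state_is_equilibrium(self, wb, wb_rest):
        from volley.models import _hh_deriv_py

        assert np.abs(_hh_deriv_py(wb_rest, wb)).max() < 1e-10
        assert wb_rest[0] < wb.spike_detection_level

    def test_resting_state_self_consistency(self, wb, wb_rest):
        tr = V.simulate_hh(wb, None, t_end=100.0, init=wb_rest)
        assert tr.spike_times.size == 0
        assert np.abs(tr.v - wb_rest[0]).max() < 0.01

    def test_rtm_resting_state(self, rtm):
        from volley.models import _hh_deriv_py

        rest = V.resting_state(rtm)
        assert rest.size == 4  # (v, m, h, n): RTM keeps sodium activation dynamic
        assert np.abs(_hh_deriv_py(rest, rtm)).max() < 1e-10

    def test_wb_strong_pulse_fires_once(self, wb):
        tr = V.simulate_hh(wb, AlphaPulse(20.0, 1.0), t_end=40.0)
        assert tr.spike_times.size == 1

    def test_wb_weak_pulse_outside_window_silent(self, wb):
        # r = 7 pulses stop triggering spikes once stretched beyond eps ~ 0.7
        tr = V.simulate_hh(wb, AlphaPulse(7.0, 1.0), t_end=200.0)
        assert tr.spike_times.size == 0

    def test_dt_halving_moves_spike_time_negligibly(self, wb):
        t1 = V.simulate_hh(wb, AlphaPulse(20.0, 1.0), 10.0, dt=0.01).spike_times[0]
        t2 = V.simulate_hh(wb, AlphaPulse(20.0, 1.0), 10.0, dt=0.005).spike_times[0]
        assert abs(t1 - t2) < 1e-4

    def test_conductance_drive_supported(self, wb):
        tr = V.simulate_hh(wb, SynapticTrain(0.1, 1.0, n_pulses=5), t_end=30.0)
        assert tr.spike_times.size >= 1

    def test_integration_failure_reports_time(self, wb):
        with pytest.raises(IntegrationError, match="non-finite"):
            V.simulate_hh(wb, DeltaTrain(w=1e308, delta=1.0, n_pulses=1), t_end=5.0)


class TestTraceAndConfig:
    def test_trace_export_roundtrip(self, lif10, tmp_path):
        import pandas as pd

        tr = simulate_lif(lif10, ConstantDrive(0.2), t_end=10.0)
        p = tmp_path / "trace.csv"
        sp = tmp_path / "spikes.csv"
        tr.export_csv(p, sp)
        df = pd.read_csv(p)
        assert list(df.columns) == ["time_ms", "v"]
        assert np.allclose(df.v.to_numpy(), tr.v)
        assert np.allclose(pd.read_csv(sp).spike_time_ms.to_numpy(), tr.spike_times)

    def test_run_config_roundtrip(self, tmp_path):
        from volley.io import dump_run_config, load_run_config

        path = tmp_path / "run.yaml"
        dump_run_config(path, V.LIFParams(10.0), dt=0.01, t_end=100.0)
        model, kw = load_run_config(path)
        assert model == V.LIFParams(10.0)
        assert kw == {"dt": 0.01, "t_end": 100.0}
        dump_run_config(path, V.HHParams.wb())
        model, _ = load_run_config(path)
        assert model_kind(model) == "wb"

    def test_lif_normalization_enforced(self):
        with pytest.raises(ValueError):
            V.LIFParams(tau=10.0, v_threshold=2.0)
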