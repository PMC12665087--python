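"""Cerenkov subtraction, ACR estimation, smoothing and sample mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scintidose import (AcrScenarioPair, BeamModel, CalibrationSet, PulseConfig,
                        PulseTrain, ScanTrajectory, cerenkov_correct,
                        effective_sampling_interval_mm, estimate_acr,
                        process_scan, pulses_to_samples, rolling_smooth,
                        scenario_pair, simulate_scan)

SETTINGS = dict(derandomize=True, max_examples=200, deadline=None)


def _train(t, rs, rc):
    return PulseTrain(np.asarray(t), np.asarray(rs), np.asarray(rc))


class TestCerenkovCorrect:
    @pytest.mark.parametrize("rs,rc,acr,expected", [
        (10.0, 2.0, 0.963, 8.074),      # direct arithmetic on the subtraction
        (7.25, 0.0, 0.963, 7.25),       # no stem light
        (0.963 * 2.0, 2.0, 0.963, 0.0), # pure Cerenkov cancels exactly
    ])
    def test_subtraction(self, rs, rc, acr, expected):
        out = cerenkov_correct(_train([0.0], [rs], [rc]), acr)
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_linear_in_both_channels(self, rng):
        rs, rc = rng.uniform(0, 10, 50), rng.uniform(0, 3, 50)
        t = np.arange(50) / 360.0
        a = cerenkov_correct(_train(t, rs, rc), 0.7)
        b = cerenkov_correct(_train(t, 2 * rs, 2 * rc), 0.7)
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)


class TestEstimateAcr:
    def test_reported_style_pair(self):
        # constructed with common true signal 4.0 and ACR 0.963
        pair = AcrScenarioPair(rs1=4.963, rc1=1.0, rs2=6.889, rc2=3.0)
        assert estimate_acr(pair) == pytest.approx(0.963, abs=1e-12)

    def test_no_sensor_difference_gives_zero(self):
        assert estimate_acr(AcrScenarioPair(5.0, 1.0, 5.0, 2.5)) == 0.0

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError, match="Cerenkov contrast"):
            estimate_acr(AcrScenarioPair(5.0, 1.0, 6.0, 1.0))

    @given(signal=st.floats(0.1, 50.0), acr=st.floats(0.0, 5.0),
           rc1=st.floats(0.0, 20.0), drc=st.floats(0.5, 20.0))
    @settings(**SETTINGS)
    def test_exact_recovery_for_common_signal(self, signal, acr, rc1, drc):
        rc2 = rc1 + drc
        pair = AcrScenarioPair(signal + acr * rc1, rc1, signal + acr * rc2, rc2)
        assert estimate_acr(pair) == pytest.approx(acr, abs=1e-9)

    def test_recovery_from_noise_free_simulation(self):
        # two wide fields deliver identical sensor dose but different
        # irradiated fiber lengths (the two-scenario construction)
        from scintidose import DetectorModel
        det = DetectorModel(acr_true=0.5)
        trains = []
        for w in (40.0, 100.0):
            traj = ScanTrajectory.station(0.0, 15.0, duration=2.0)
            trains.append(simulate_scan(BeamModel(field_width_w=w), det, traj,
                                        PulseConfig(360.0, 0.0, 1)))
        assert estimate_acr(scenario_pair(*trains)) == pytest.approx(0.5, abs=1e-12)


class TestRollingSmooth:
    def test_three_point_example_with_shrinking_edges(self):
        t = np.array([0.0, 1e-3, 2e-3])
        out = rolling_smooth(t, [0.0, 3.0, 6.0], window_ms=3.0)
        np.testing.assert_allclose(out, [1.5, 3.0, 4.5], atol=1e-12)

    def test_constant_series_unchanged(self):
        t = np.arange(100) / 360.0
        np.testing.assert_array_equal(rolling_smooth(t, np.full(100, 5.0)),
                                      np.full(100, 5.0))

    @given(a=st.floats(-5.0, 5.0), b=st.floats(-10.0, 10.0))
    @settings(**SETTINGS)
    def test_commutes_with_affine_scaling(self, a, b):
        rng = np.random.default_rng(5)
        t = np.arange(200) / 360.0
        v = rng.normal(50.0, 5.0, 200)
        lhs = rolling_smooth(t, a * v + b)
        rhs = a * rolling_smooth(t, v) + b
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_white_noise_variance_reduced_by_window_count(self, rng):
        n, var = 20000, 4.0
        t = np.arange(n) * 1e-3
        v = rng.normal(0.0, np.sqrt(var), n)
        out = rolling_smooth(t, v, window_ms=15.0)  # 15 pulses per window
        interior = out[50:-50]
        assert np.var(interior) == pytest.approx(var / 15.0, rel=0.2)

    def test_empty_and_bad_window_rejected(self):
        with pytest.raises(ValueError):
            rolling_smooth(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            rolling_smooth(np.array([0.0]), np.array([1.0]), window_ms=0.0)


class TestPulsesToSamples:
    @pytest.mark.parametrize("speed,expected", [(10.0, 0.4), (20.0, 0.8)])
    def test_effective_sampling_interval(self, speed, expected):
        assert effective_sampling_interval_mm(speed, 40.0) == pytest.approx(expected)

    @pytest.mark.parametrize("speed,expected", [(10.0, 0.4), (20.0, 0.8)])
    def test_empirical_window_support_on_simulated_scan(self, speed, expected,
                                                        beam3x3, detector, cal):
        traj = ScanTrajectory.profile_scan(-25.0, 25.0, speed, depth=13.0)
        train = simulate_scan(beam3x3, detector, traj, PulseConfig(360.0, 0.0, 2))
        half = 0.040 / 2.0
        lo = np.searchsorted(train.t, train.t - half, side="left")
        hi = np.searchsorted(train.t, train.t + half, side="right")
        support = (hi - lo) / 360.0 * speed  # mm swept by each smoothing window
        interior = support[20:-20]
        spacing = speed / 360.0
        assert np.all(np.abs(interior - expected) <= spacing + 1e-12)

    def test_sample_spacing_is_speed_over_prf(self, beam3x3, detector, cal):
        traj = ScanTrajectory.profile_scan(-10.0, 10.0, 10.0, depth=13.0)
        train = simulate_scan(beam3x3, detector, traj, PulseConfig(360.0, 0.0, 2))
        curve = process_scan(train, traj, cal)
        assert len(curve) == len(train)
        np.testing.assert_allclose(np.diff(curve.abscissa), 10.0 / 360.0, rtol=1e-9)

    def test_stationary_scan_maps_to_start(self, cal):
        traj = ScanTrajectory.station(-3.0, 15.0, duration=1.0)
        t = np.arange(100) / 360.0
        df = pulses_to_samples(t, np.ones(100), traj, cal)
        assert np.all(df["position_mm"].to_numpy() == -3.0)

    def test_invertible_for_moving_scan(self, cal):
        traj = ScanTrajectory.profile_scan(-10.0, 10.0, 10.0, depth=13.0)
        t = np.arange(700) / 360.0
        df = pulses_to_samples(t, np.ones(700), traj, cal)
        t_back = traj.t0 + (df["position_mm"].to_numpy() - traj.start) / traj.speed
        np.testing.assert_allclose(t_back, t, atol=1e-9)

    def test_times_outside_span_rejected(self, cal):
        traj = ScanTrajectory.profile_scan(-10.0, 10.0, 10.0, depth=13.0)
        with pytest.raises(ValueError, match="outside"):
            pulses_to_samples(np.array([0.0, 5.0]), np.array([1.0, 1.0]), traj, cal)

    def test_process_scan_needs_motion(self, beam3x3, detector, cal):
        traj = ScanTrajectory.station(0.0, 15.0, duration=1.0)
        train = simulate_scan(beam3x3, detector, traj, PulseConfig(360.0, 0.0, 2))
        with pytest.raises(ValueError, match="moving"):
            process_scan(train, traj, cal)
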