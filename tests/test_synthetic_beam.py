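"""Ground-truth beam model and pulse-train simulator."""

import math

import numpy as np
import pytest

from conftest import Z_8020
from scintidose import (BeamModel, DetectorModel, PulseConfig, ScanTrajectory,
                        averaged_dose, cerenkov_correct, dose_at,
                        ground_truth_profile, irradiated_fiber_length,
                        normalize_profile, pdd_model, penumbra_widths,
                        profile_model, simulate_scan, volume_average)


class TestPddModel:
    def test_maximum_is_exactly_100_at_dmax(self, beam3x3):
        # for mu > 0 and the default parameters the peak sits at d_max
        assert pdd_model(beam3x3.d_max, beam3x3) == pytest.approx(100.0, abs=1e-12)
        depths = np.linspace(0.0, 350.0, 3000)
        assert pdd_model(depths, beam3x3).max() <= 100.0 + 1e-9

    def test_exponential_falloff_ratio_closed_form(self, beam3x3):
        # mu=0.004/mm over 100 mm beyond d_max: the stated formula gives
        # exp(-0.4) * (1 - e^{-46}) / (1 - e^{-6})
        ratio = pdd_model(115.0, beam3x3) / pdd_model(15.0, beam3x3)
        exact = math.exp(-0.4) * (1 - math.exp(-0.4 * 115)) / (1 - math.exp(-6.0))
        assert ratio == pytest.approx(exact, rel=1e-12)
        assert ratio == pytest.approx(math.exp(-0.4), rel=5e-3)

    def test_monotone_decay_beyond_dmax(self, beam3x3):
        depths = np.linspace(beam3x3.d_max, 350.0, 500)
        assert np.all(np.diff(pdd_model(depths, beam3x3)) < 0.0)

    def test_negative_depth_rejected(self, beam3x3):
        with pytest.raises(ValueError):
            pdd_model(-1.0, beam3x3)


class TestProfileModel:
    def test_cax_normalization(self, beam3x3):
        for depth in (0.0, 13.0, 100.0):
            bx = beam3x3.offset_x0  # untilted
            assert profile_model(bx, depth, beam3x3) == pytest.approx(100.0, abs=1e-9)

    def test_half_value_at_geometric_edge(self):
        beam = BeamModel(field_width_w=100.0, penumbra_sigma=2.0)
        for edge in (-50.0, 50.0):
            assert profile_model(edge, 0.0, beam) == pytest.approx(50.0, abs=1e-6)

    def test_symmetry_without_tilt_or_offset(self, beam3x3):
        x = np.linspace(0.0, 40.0, 801)
        np.testing.assert_allclose(profile_model(x, 50.0, beam3x3),
                                   profile_model(-x, 50.0, beam3x3), atol=1e-12)

    def test_erf_edge_penumbra_matches_normal_quantiles(self):
        beam = BeamModel(field_width_w=80.0, penumbra_sigma=2.0)
        x = np.arange(-60.0, 60.0, 0.01)
        from scintidose import Curve
        prof = Curve(x, profile_model(x, 0.0, beam), "profile")
        pen = penumbra_widths(prof)
        assert pen.mean_mm == pytest.approx(Z_8020 * 2.0, rel=1e-3)

    def test_bounded_by_100(self, beam3x3):
        x = np.linspace(-60.0, 60.0, 2401)
        assert profile_model(x, 20.0, beam3x3).max() <= 100.0 + 1e-9


class TestDoseAt:
    def test_cax_dmax_returns_per_pulse_output(self, beam3x3):
        assert dose_at(0.0, beam3x3.d_max, beam3x3) == pytest.approx(
            beam3x3.output_cGy_per_pulse, rel=1e-12)

    def test_linearity_in_output(self, beam3x3):
        double = BeamModel(field_width_w=30.0, output_cGy_per_pulse=0.1)
        x = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(dose_at(x, 50.0, double),
                                   2.0 * dose_at(x, 50.0, beam3x3), rtol=1e-12)

    def test_tilt_moves_argmax_to_beam_axis(self):
        # small field: the FFF-like apex is sharp enough to localize
        beam = BeamModel(field_width_w=5.0, tilt_theta=0.01)
        x = np.arange(1.0, 3.0, 5e-4)
        am = x[np.argmax(dose_at(x, 200.0, beam))]
        assert am == pytest.approx(200.0 * math.tan(0.01), abs=1e-3)


class TestSimulateScan:
    def test_pulse_count(self, beam3x3, detector):
        traj = ScanTrajectory.station(0.0, 15.0, duration=10.0)
        train = simulate_scan(beam3x3, detector, traj, PulseConfig(360.0, 0.0, 0))
        assert len(train) == 3600

    def test_noise_free_limit_recovers_dose(self, beam3x3):
        det = DetectorModel(fiber_cerenkov_coeff=0.0, cr_true=1.0, length_mm=1e-6)
        traj = ScanTrajectory.profile_scan(-25.0, 25.0, 10.0, depth=13.0)
        train = simulate_scan(beam3x3, det, traj, PulseConfig(360.0, 0.0, 1))
        x, d = traj.position(train.t)
        np.testing.assert_allclose(train.rs, dose_at(x, d, beam3x3), rtol=1e-9)
        assert np.all(train.rc == 0.0)

    def test_sensor_channel_equals_averaged_dose_exactly(self, beam3x3, detector):
        traj = ScanTrajectory.profile_scan(-25.0, 25.0, 10.0, depth=13.0)
        train = simulate_scan(beam3x3, detector, traj, PulseConfig(360.0, 0.0, 1))
        x, d = traj.position(train.t)
        truth = averaged_dose(x, d, beam3x3, detector)
        np.testing.assert_allclose(
            cerenkov_correct(train, detector.acr_true) * detector.cr_true,
            truth, rtol=1e-12)

    def test_seeded_determinism(self, beam3x3, detector):
        traj = ScanTrajectory.profile_scan(-25.0, 25.0, 10.0, depth=13.0)
        cfg = PulseConfig(360.0, 0.02, 42)
        a = simulate_scan(beam3x3, detector, traj, cfg)
        b = simulate_scan(beam3x3, detector, traj, cfg)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.rs, b.rs) \
            and np.array_equal(a.rc, b.rc)

    def test_station_scan_mean_within_monte_carlo_error(self, beam3x3, detector, cal):
        cv = 0.02
        traj = ScanTrajectory.station(0.0, beam3x3.d_max, duration=10.0)
        train = simulate_scan(beam3x3, detector, traj, PulseConfig(360.0, cv, 7))
        mean = float((cerenkov_correct(train, cal.acr) * cal.cr).mean())
        n = len(train)
        bound = 3.0 * cv / math.sqrt(n) * beam3x3.output_cGy_per_pulse
        assert abs(mean - beam3x3.output_cGy_per_pulse) < bound

    def test_too_short_trajectory_rejected(self, beam3x3, detector):
        traj = ScanTrajectory.station(0.0, 15.0, duration=1e-4)
        with pytest.raises(ValueError):
            simulate_scan(beam3x3, detector, traj, PulseConfig(360.0, 0.0, 0))


class TestFiberAndVolume:
    def test_irradiated_length_is_infield_overlap(self, detector):
        beam = BeamModel(field_width_w=40.0)  # half-width 20 at the surface
        assert irradiated_fiber_length(0.0, 0.0, beam, detector) == pytest.approx(20.0)
        assert irradiated_fiber_length(-25.0, 0.0, beam, detector) == 0.0
        short = DetectorModel(fiber_length_mm=5.0)
        assert irradiated_fiber_length(0.0, 0.0, beam, short) == pytest.approx(5.0)

    def test_volume_averaging_softens_but_never_amplifies(self, beam3x3):
        from scintidose import Curve
        x = np.arange(-40.0, 40.0, 0.01)
        prof = Curve(x, profile_model(x, 0.0, beam3x3), "profile")
        for length in (0.5, 1.0, 2.0):
            avg = volume_average(prof, length)
            assert avg.values.max() <= prof.values.max() * (1.0 + 1e-9)
            assert penumbra_widths(avg).mean_mm >= penumbra_widths(prof).mean_mm

    def test_averaged_penumbra_matches_quadrature_sigma(self, beam3x3, detector):
        # rectangular kernel of width L adds L^2/12 to the edge variance
        x = np.arange(-40.0, 40.0, 0.01)
        prof = ground_truth_profile(beam3x3, x, beam3x3.d_max, detector)
        pen = penumbra_widths(normalize_profile(prof, 0.0))
        sigma_eff = math.sqrt(beam3x3.penumbra_sigma ** 2
                              + detector.length_mm ** 2 / 12.0)
        assert pen.mean_mm == pytest.approx(Z_8020 * sigma_eff, rel=5e-3)
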