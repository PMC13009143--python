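"""Velocity model, Poiseuille fitting, volume rates, waveform biomarkers."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import retiflow as rf
from retiflow.containers import Calibration, CrossSection, Waveform
from retiflow.errors import InvalidSpecError, NoCyclesError
from retiflow.hemodynamics import (VelocityVideo, biomarkers,
                                   branch_volume_rate, cycle_filter,
                                   detect_cycles, fit_poiseuille,
                                   mean_time_profile, quantify,
                                   total_volume_rate,
                                   velocity_from_broadening)
from retiflow.units import flow_ul_min


class TestVelocityModel:
    def test_hand_computed_default_calibration(self):
        # 5 * 852 nm * 5000 Hz / 0.25 = 85.2 mm/s
        assert velocity_from_broadening(5000.0) == pytest.approx(85.2)

    def test_zero_broadening_zero_velocity(self):
        assert velocity_from_broadening(0.0) == 0.0

    def test_negative_broadening_clipped(self):
        assert velocity_from_broadening(-3000.0) == 0.0

    @given(df=st.floats(0.0, 5e4))
    def test_linearity(self, df):
        assert velocity_from_broadening(2 * df) == pytest.approx(
            2 * velocity_from_broadening(df), rel=1e-12)


class TestPoiseuilleFit:
    def test_exact_parabola_recovered(self):
        x = np.arange(17, dtype=float)
        prof = 40.0 * np.clip(1 - ((x - 8.0) / 5.0) ** 2, 0, None)
        fit = fit_poiseuille(prof, pixel_size_um=8.37)
        assert fit.ok
        assert fit.diameter_um == pytest.approx(83.7, rel=1e-9)
        assert fit.v_max == pytest.approx(40.0, rel=1e-9)
        assert fit.center_px == pytest.approx(8.0, abs=1e-9)
        assert fit.residual < 1e-9

    def test_scaling_leaves_geometry_bit_identical(self):
        x = np.arange(15, dtype=float)
        prof = 25.0 * np.clip(1 - ((x - 7.2) / 4.1) ** 2, 0, None)
        f1 = fit_poiseuille(prof, 10.0)
        f2 = fit_poiseuille(2 * prof, 10.0)
        assert f2.diameter_um == f1.diameter_um
        assert f2.center_px == f1.center_px
        assert f2.v_max == pytest.approx(2 * f1.v_max, rel=1e-12)

    def test_noisy_parabola_median_error_under_5_percent(self):
        x = np.arange(17, dtype=float)
        truth = 30.0 * np.clip(1 - ((x - 8.0) / 5.0) ** 2, 0, None)
        rng = np.random.default_rng(0)
        errors = []
        for _ in range(100):
            prof = truth + rng.normal(0, 0.05 * 30.0, truth.size)
            fit = fit_poiseuille(prof, 10.0)
            errors.append(abs(fit.diameter_um - 100.0) / 100.0)
        assert np.median(errors) < 0.05

    def test_degenerate_profiles_flagged(self):
        assert not fit_poiseuille(np.zeros(9), 10.0).ok
        assert not fit_poiseuille(np.arange(9.0), 10.0).ok  # monotone

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidSpecError):
            fit_poiseuille(np.array([0.0, 1.0, 0.0]), 10.0)


def make_section(center=(16.0, 16.0), direction=(1.0, 0.0), half_length=8):
    return CrossSection(branch_id=1, center=center, direction=direction,
                        half_length=half_length)


class TestProfilesAndFlow:
    def test_time_constant_field_profile(self):
        v = np.tile(np.linspace(0, 1, 32)[:, None, None], (1, 32, 10))
        vel = VelocityVideo(v=v, window_times_s=np.arange(10.0),
                            pixel_size_um=10.0)
        sec = make_section()
        prof = mean_time_profile(vel, sec)
        np.testing.assert_allclose(prof, v[8:25, 16, 0], atol=1e-12)

    def test_integer_cycle_ripple_cancels(self):
        base = np.ones((32, 32))
        ripple = np.sin(2 * np.pi * np.arange(40) / 10)  # 4 full cycles
        v = base[:, :, None] * (1.0 + 0.3 * ripple)[None, None, :]
        vel = VelocityVideo(v=v, window_times_s=np.arange(40.0),
                            pixel_size_um=10.0)
        prof = mean_time_profile(vel, make_section())
        np.testing.assert_allclose(prof, 1.0, rtol=1e-6)

    def test_single_section_flow_oracle(self, phantom, phantom_calib):
        # v_bar = 10 mm/s through d = 100 um -> 4.71 uL/min
        q = flow_ul_min(10.0, np.pi * 50.0**2)
        assert q == pytest.approx(4.712, abs=1e-3)

    def test_section_outside_image_rejected(self):
        vel = VelocityVideo(v=np.zeros((16, 16, 4)),
                            window_times_s=np.arange(4.0), pixel_size_um=10.0)
        with pytest.raises(InvalidSpecError):
            mean_time_profile(vel, make_section(center=(15.0, 15.0)))

    def test_total_volume_rate_sums_branches(self):
        t = np.arange(20.0)
        f = np.sin(t) + 2.0
        total = total_volume_rate({1: f, 2: f, 3: f}, t)
        np.testing.assert_allclose(total.value, 3 * f)
        single = total_volume_rate({1: f}, t)
        np.testing.assert_allclose(single.value, f)

    def test_mismatched_time_bases_rejected(self):
        with pytest.raises(InvalidSpecError):
            total_volume_rate({1: np.ones(5)}, np.arange(4.0))

    def test_branch_flow_matches_ground_truth(self, phantom, phantom_map,
                                              phantom_calib):
        from retiflow.hemodynamics import _background_series
        _, video, truth = phantom
        bg = _background_series(video, phantom_map)
        for bid in phantom_map.branch_ids:
            secs = [s for s in phantom_map.sections if s.branch_id == bid]
            q = branch_volume_rate(video, secs, bg, phantom_calib)
            true_bid = max(truth.branch_masks, key=lambda k: np.sum(
                (phantom_map.branch_labels == bid) & truth.branch_masks[k]))
            assert q.mean() == pytest.approx(
                truth.per_branch_qm_ul_min[true_bid], rel=0.05)


class TestCycles:
    def test_sinusoid_heart_rate_and_systole_count(self):
        t = np.arange(0, 4.0, 1 / 128.0)
        w = Waveform(t=t, value=np.sin(2 * np.pi * 1.5 * t) + 2.0,
                     kind="volume_rate")
        out = detect_cycles(w)
        assert out.heart_rate_bpm == pytest.approx(90.0, abs=0.5)
        assert len(out.systole_idx) == 6

    def test_flat_waveform_raises_no_cycles(self):
        w = Waveform(t=np.arange(100.0), value=np.full(100, 3.0),
                     kind="volume_rate")
        with pytest.raises(NoCyclesError):
            detect_cycles(w)

    def test_cardiac_waveform_notch_not_counted(self):
        spec = rf.CardiacWaveformSpec(heart_rate_bpm=75.0, duration_s=4.8,
                                      dicrotic_notch_depth=0.3)
        fs = 130.0
        w = Waveform(t=np.arange(int(4.8 * fs)) / fs,
                     value=rf.make_cardiac_waveform(spec, fs),
                     kind="velocity")
        out = detect_cycles(w)
        assert out.heart_rate_bpm == pytest.approx(75.0, abs=1.0)
        assert len(out.systole_idx) == 6  # one systole per cycle, no notches


class TestCycleFilter:
    def _smooth_wave(self, hr=75.0, seconds=5.0, fs=130.0):
        spec = rf.CardiacWaveformSpec(heart_rate_bpm=hr, duration_s=seconds)
        t = np.arange(int(seconds * fs)) / fs
        return Waveform(t=t, value=rf.make_cardiac_waveform(spec, fs),
                        kind="velocity")

    def test_smooth_waveform_nearly_unchanged(self):
        w = detect_cycles(self._smooth_wave())
        out = cycle_filter(w)
        # compare on the common (cropped) support
        lo = np.searchsorted(w.t, out.t[0])
        ref = w.value[lo:lo + out.value.size]
        assert np.max(np.abs(out.value - ref)) / np.max(ref) < 0.01

    def test_high_frequency_noise_attenuated(self):
        w = self._smooth_wave()
        f_noise = 25 * 75.0 / 60.0  # 25x the heart rate
        noise = 0.05 * np.sin(2 * np.pi * f_noise * w.t)
        noisy = detect_cycles(Waveform(t=w.t, value=w.value + noise,
                                       kind="velocity"))
        out = cycle_filter(noisy)
        lo = np.searchsorted(w.t, out.t[0])
        ref = w.value[lo:lo + out.value.size]
        residual = out.value - ref
        assert np.std(residual) < np.std(noise) / 10

    def test_crop_keeps_integer_cycle_count(self):
        # 4.6 cycles in -> exactly 4 cycles between first and last systole
        w = detect_cycles(self._smooth_wave(hr=60.0, seconds=4.6))
        out = cycle_filter(w)
        assert len(out.systole_idx) == 5
        span = out.t[out.systole_idx[-1]] - out.t[out.systole_idx[0]]
        assert span == pytest.approx(4.0, abs=0.05)


class TestBiomarkers:
    def _annotated(self, value, t):
        return detect_cycles(Waveform(t=t, value=value, kind="volume_rate"))

    def test_ri_pi_from_known_extrema(self):
        # systolic 2, diastolic 1, mean 1.5 -> RI 0.5, PI 2/3
        t = np.arange(0, 4.0, 1 / 200.0)
        q = 1.5 + 0.5 * np.sin(2 * np.pi * t)
        w = self._annotated(q, t)
        m = biomarkers(w, w, [100.0])
        assert m.ri_q == pytest.approx(0.5, abs=1e-3)
        assert m.pi_q == pytest.approx(2 / 3, abs=1e-3)

    def test_stroke_volume_closed_form(self):
        # q = 40 + 30 sin(2 pi t) uL/min (= 666.7 + 500 sin, nL/s):
        # integral from max-derivative (t=0 mod 1) to peak (t=0.25) is
        # 40*0.25 + 30/(2 pi) in uL/min*s -> 246.3 nL
        t = np.arange(0, 3.0, 1 / 500.0)
        q = 40.0 + 30.0 * np.sin(2 * np.pi * t)
        w = self._annotated(q, t)
        m = biomarkers(w, w, [100.0])
        assert m.vas_nl == pytest.approx(246.3, rel=0.005)

    def test_missing_annotation_rejected(self):
        w = Waveform(t=np.arange(10.0), value=np.ones(10), kind="volume_rate")
        with pytest.raises(NoCyclesError):
            biomarkers(w, w, [100.0])

    def test_ordering_and_index_invariants(self, phantom, phantom_map,
                                           phantom_calib):
        _, video, _ = phantom
        m, _, _ = quantify(video, phantom_map, phantom_calib)
        assert m.qd_ul_min <= m.qm_ul_min <= m.qs_ul_min
        assert 0.0 <= m.ri_q <= 1.0
        assert m.pi_q >= m.ri_q
        assert m.pi_v >= m.ri_v

    def test_diameter_sensitivity_is_quadratic(self, phantom, phantom_map,
                                               phantom_calib):
        # +-2% diameter perturbation must move QM by less than +-4.1%
        import copy
        _, video, _ = phantom
        base, _, _ = quantify(video, copy.deepcopy(phantom_map),
                              phantom_calib)
        for eps in (0.98, 1.02):
            amap = copy.deepcopy(phantom_map)
            pert, _, _ = quantify(
                video, amap,
                Calibration(pixel_size_um=phantom_calib.pixel_size_um * eps))
            # pixel-size rescaling scales every fitted diameter by eps
            ratio = pert.qm_ul_min / base.qm_ul_min
            assert abs(ratio - 1.0) <= abs(eps**2 - 1.0) + 1e-9


class TestEndToEnd:
    def test_noiseless_phantom_parameter_recovery(self, phantom, phantom_map,
                                                  phantom_calib):
        _, video, truth = phantom
        m, _, _ = quantify(video, phantom_map, phantom_calib)
        true_diam = np.mean(list(truth.true_diameters_um.values()))
        assert m.qm_ul_min == pytest.approx(truth.total_qm_ul_min, rel=0.05)
        assert m.ri_q == pytest.approx(truth.true_ri, abs=0.05)
        assert m.ri_v == pytest.approx(truth.true_ri, abs=0.05)
        assert m.mean_diameter_um == pytest.approx(true_diam, rel=0.03)
        assert m.heart_rate_bpm == pytest.approx(truth.true_h_bpm, abs=1.0)
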