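"""Motion checkerboard stimulus: geometry, motion, rendering, discretization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ffsmvep as fm
from ffsmvep.stimulus import InvalidProfileError


def annulus_mask(geometry, resolution=200):
    n = resolution
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    scale = geometry.outer_radius_px / (n / 2.0)
    r = np.hypot((xx - c) * scale, (c - yy) * scale)
    return (r >= geometry.inner_radius_px) & (r <= geometry.outer_radius_px)


class TestMotionProfile:
    def test_displacement_starts_at_rest_and_peaks_mid_cycle(self):
        p = fm.MotionProfile(reversal_freq_hz=8.0, amplitude_px=10.0)
        assert fm.radial_displacement(p, 0.0) == pytest.approx(0.0)
        # the 4 Hz modulation sinusoid reaches the extremum at half its cycle
        assert fm.radial_displacement(p, 0.125) == pytest.approx(10.0)

    def test_direction_changes_at_reversal_rate(self):
        # two direction changes per 4 Hz modulation cycle -> 8 per second
        p = fm.MotionProfile(reversal_freq_hz=8.0, amplitude_px=10.0)
        dt = 1e-5
        t = np.arange(0, 1.0 + 2 * dt, dt)  # cover the reversal at t = 1.0
        v = np.diff(fm.radial_displacement(p, t))
        sign_changes = np.sum(np.diff(np.sign(v[np.abs(v) > 1e-12])) != 0)
        assert sign_changes == 8

    @given(st.floats(0.0, 10.0), st.floats(2.0, 30.0), st.floats(1.0, 20.0))
    @settings(deadline=None, max_examples=50)
    def test_displacement_periodic_and_bounded(self, t, f_rev, amp):
        p = fm.MotionProfile(f_rev, amp)
        s = fm.radial_displacement(p, t)
        assert 0.0 <= s <= amp + 1e-9
        period = 1.0 / p.cycle_freq_hz
        assert fm.radial_displacement(p, t + period) == pytest.approx(s, abs=1e-6 * amp)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(InvalidProfileError):
            fm.MotionProfile(reversal_freq_hz=0.0)
        with pytest.raises(InvalidProfileError):
            fm.MotionProfile(reversal_freq_hz=8.0, amplitude_px=-1.0)


class TestRenderFrame:
    def test_background_outside_annulus(self, geometry):
        frame = fm.render_frame(geometry, 0.0, resolution=200)
        assert frame[0, 0] == geometry.l_min  # corner is outside the outer radius
        centre = frame[100, 100]
        assert centre == geometry.l_min  # inside the inner radius

    def test_equal_bright_dark_area(self, geometry):
        mask = annulus_mask(geometry)
        for disp in (0.0, 1.7, 3.3, 7.5):
            frame = fm.render_frame(geometry, disp, resolution=200)
            frac = (frame[mask] == geometry.l_max).mean()
            assert frac == pytest.approx(0.5, abs=0.02)

    def test_periodic_in_two_ring_widths(self, geometry):
        f0 = fm.render_frame(geometry, 0.0)
        f2 = fm.render_frame(geometry, 2 * geometry.ring_width_px)
        np.testing.assert_array_equal(f0, f2)

    def test_luminance_values_within_geometry_range(self):
        g = fm.StimulusGeometry(l_max=0.625, l_min=0.375)
        frame = fm.render_frame(g, 3.0)
        assert set(np.unique(frame)) <= {g.l_min, g.l_max}


class TestRenderSequence:
    def test_frame_count(self, geometry):
        seq = fm.render_sequence(geometry, fm.MotionProfile(8.0), 144.0, 1.0, resolution=64)
        assert seq.n_frames == 144

    def test_flicker_free_mean_luminance(self, geometry):
        seq = fm.render_sequence(geometry, fm.MotionProfile(15.6), 144.0, 1.0, resolution=200)
        lum = seq.mean_luminance()
        assert lum.std() / lum.mean() < 0.01

    def test_deterministic(self, geometry):
        a = fm.render_sequence(geometry, fm.MotionProfile(8.0), 60.0, 0.5, resolution=64)
        b = fm.render_sequence(geometry, fm.MotionProfile(8.0), 60.0, 0.5, resolution=64)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_nonpositive_duration_rejected(self, geometry):
        with pytest.raises(ValueError):
            fm.render_sequence(geometry, fm.MotionProfile(8.0), 144.0, 0.0)

    def test_subnyquist_refresh_warns(self, geometry):
        with pytest.warns(UserWarning, match="aliased"):
            fm.render_sequence(geometry, fm.MotionProfile(40.0), 60.0, 0.2, resolution=32)


class TestSampledSignal:
    def test_high_refresh_limit_matches_continuous(self):
        p = fm.MotionProfile(15.6, 10.0)
        held = fm.sampled_motion_signal(p, 1e6, 1.0, eval_rate_hz=7200.0)
        cont = fm.continuous_motion_signal(p, 1.0, eval_rate_hz=7200.0)
        rms = np.sqrt(np.mean((held.values - cont.values) ** 2))
        assert rms < 1e-3 * p.amplitude_px

    def test_rms_error_monotone_in_refresh_rate(self):
        p = fm.MotionProfile(15.6, 10.0)
        cont = fm.continuous_motion_signal(p, 2.0)
        errs = []
        for refresh in (60.0, 120.0, 144.0, 240.0):
            held = fm.sampled_motion_signal(p, refresh, 2.0)
            errs.append(np.sqrt(np.mean((held.values - cont.values) ** 2)))
        assert all(a >= b for a, b in zip(errs, errs[1:]))
        assert errs[0] > errs[2]  # 60 Hz strictly worse than 144 Hz

    def test_low_refresh_has_larger_spurious_spectral_content(self):
        p = fm.MotionProfile(15.6, 10.0)

        def largest_spurious(refresh):
            sig = fm.sampled_motion_signal(p, refresh, 2.0)
            spec = fm.amplitude_spectrum(sig.values - sig.values.mean(), sig.rate_hz)
            off_fundamental = np.abs(spec.freqs_hz - p.cycle_freq_hz) > 2.0
            return spec.amplitudes[off_fundamental & (spec.freqs_hz > 1.0)].max()

        assert largest_spurious(60.0) > largest_spurious(144.0)

    def test_rectified_velocity_peaks_at_reversal_frequency(self):
        # motion speed |ds/dt| at the 144 Hz frame rate oscillates at the
        # reversal frequency: the response fundamental the paradigm relies on
        for f_rev in (4.0, 8.0, 15.6):
            p = fm.MotionProfile(f_rev, 10.0)
            sig = fm.continuous_motion_signal(p, 2.0, eval_rate_hz=144.0)
            speed = np.abs(np.gradient(sig.values))
            spec = fm.amplitude_spectrum(speed - speed.mean(), sig.rate_hz)
            assert spec.peak_freq() == pytest.approx(f_rev, abs=spec.resolution_hz)


class TestScalars:
    @pytest.mark.parametrize(
        "l_max, l_min, expected",
        [(1.0, 0.0, 1.0), (0.7, 0.7, 0.0), (0.625, 0.375, 0.25)],
    )
    def test_michelson_contrast(self, l_max, l_min, expected):
        assert fm.michelson_contrast(l_max, l_min) == pytest.approx(expected)

    def test_zero_luminance_contrast_undefined(self):
        with pytest.raises(ZeroDivisionError):
            fm.michelson_contrast(0.0, 0.0)

    def test_visual_angle_reference_setup(self):
        # 100 px of 0.31 mm pixels at 800 mm
        assert fm.visual_angle_deg(100, 0.31, 800, pi=3.14) == pytest.approx(2.22, abs=0.005)
        assert fm.visual_angle_deg(0, 0.31, 800) == 0.0
        near = fm.visual_angle_deg(100, 0.31, 800)
        far = fm.visual_angle_deg(100, 0.31, 1600)
        assert near == pytest.approx(2 * far)


class TestGeometryValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"outer_diameter_px": 20.0, "inner_diameter_px": 100.0},
            {"n_sectors": 15},
            {"n_rings": 0},
            {"l_max": 0.2, "l_min": 0.8},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fm.StimulusGeometry(**kwargs)
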