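"""Pupillometry pipeline: inversion, thresholding, region filtering,
reconnection/ellipse fitting, and the filtered diameter time series."""

import numpy as np
import pytest
from scipy import signal
from skimage import measure

from mousephys import pupil, synth
from conftest import render_pupil


def frame8(arr):
    return pupil.GrayFrame(np.asarray(arr, dtype=np.uint8))


class TestInvert:
    def test_extremes_and_values(self):
        f = frame8(np.full((4, 4), 0))
        assert np.all(pupil.invert_image(f).pixels == 255)
        f = frame8(np.full((4, 4), 100))
        assert np.all(pupil.invert_image(f).pixels == 155)

    def test_involution_bit_exact(self):
        rng = np.random.default_rng(0)
        f = frame8(rng.integers(0, 256, (32, 48)))
        twice = pupil.invert_image(pupil.invert_image(f))
        assert np.array_equal(twice.pixels, f.pixels)

    def test_preserves_timestamp_and_16bit_range(self):
        f = pupil.GrayFrame(np.array([[0, 65535]], dtype=np.uint16), timestamp=2.5)
        out = pupil.invert_image(f)
        assert out.timestamp == 2.5
        assert out.pixels.tolist() == [[65535, 0]]

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            pupil.GrayFrame(np.empty((0, 5), dtype=np.uint8))


class TestBinarize:
    def test_fixed_threshold_ge_convention(self):
        cfg = pupil.PupilConfig(threshold_mode="fixed", fixed_threshold=100)
        below = frame8(np.full((4, 4), 99))
        assert not pupil.binarize(below, cfg).any()
        boundary = frame8(np.full((4, 4), 100))
        assert pupil.binarize(boundary, cfg).all()
        two = frame8(np.array([[50, 200], [200, 50]]))
        assert pupil.binarize(two, cfg).tolist() == [[False, True], [True, False]]

    def test_fixed_threshold_out_of_range(self):
        cfg = pupil.PupilConfig(threshold_mode="fixed", fixed_threshold=300)
        with pytest.raises(ValueError):
            pupil.binarize(frame8(np.zeros((4, 4))), cfg)

    def test_auto_on_uniform_frame_yields_empty_mask(self, cfg):
        assert not pupil.binarize(frame8(np.full((10, 10), 128)), cfg).any()

    def test_auto_isolates_brightest_class(self, cfg):
        # inverted three-level scene: background 55, iris 105, pupil 225
        img = np.full((60, 60), 55, dtype=np.uint8)
        img[10:50, 10:50] = 105
        img[25:35, 25:35] = 225
        mask = pupil.binarize(frame8(img), cfg)
        assert mask[25:35, 25:35].all()
        assert mask.sum() == 100


class TestExtractRegions:
    def test_empty_mask(self, cfg):
        assert pupil.extract_regions(np.zeros((20, 20), bool), cfg) == []

    def test_disk_kept_line_removed(self, cfg):
        mask = np.zeros((100, 160), bool)
        Y, X = np.ogrid[:100, :160]
        mask[(X - 50) ** 2 + (Y - 50) ** 2 <= 20**2] = True  # disk r=20
        mask[10, 100:150] = True  # 1x50 line: circularity ~ 4*pi*50/P^2 << 0.3
        regions = pupil.extract_regions(mask, cfg)
        assert len(regions) == 1
        assert regions[0].circularity >= 0.8
        assert regions[0].area == pytest.approx(np.pi * 400, rel=0.02)

    def test_small_area_removed(self, cfg):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:12] = True  # 35 px^2 < min_area 50
        assert pupil.extract_regions(mask, cfg) == []

    def test_sorted_by_decreasing_area_and_circularity_bounds(self, cfg):
        mask = np.zeros((120, 120), bool)
        Y, X = np.ogrid[:120, :120]
        mask[(X - 30) ** 2 + (Y - 30) ** 2 <= 10**2] = True
        mask[(X - 80) ** 2 + (Y - 80) ** 2 <= 25**2] = True
        regions = pupil.extract_regions(mask, cfg)
        areas = [r.area for r in regions]
        assert areas == sorted(areas, reverse=True)
        for r in regions:
            assert cfg.min_circularity <= r.circularity <= 1.0


class TestReconnectAndFit:
    def test_no_regions_absent(self, cfg):
        fit, n = pupil.reconnect_and_fit([], cfg)
        assert fit is None and n == 0

    def test_single_ellipse_minor_axis(self, cfg):
        frame, truth = render_pupil(24, major=40)
        inv = pupil.invert_image(frame)
        regions = pupil.extract_regions(pupil.binarize(inv, cfg), cfg)
        fit, n = pupil.reconnect_and_fit(regions, cfg)
        assert n == 1
        assert fit.minor_axis_length == pytest.approx(24, abs=1)
        assert fit.major_axis_length == pytest.approx(40, abs=1)
        assert fit.major_axis_length >= fit.minor_axis_length

    def test_split_ellipse_reconnected(self, cfg):
        frame, truth = render_pupil(
            24, major=40, occluder=synth.Occluder(orientation=np.pi / 2, width=3)
        )
        inv = pupil.invert_image(frame)
        regions = pupil.extract_regions(pupil.binarize(inv, cfg), cfg)
        assert len(regions) == 2
        fit, n = pupil.reconnect_and_fit(regions, cfg)
        assert n == 2
        assert fit.minor_axis_length == pytest.approx(24, abs=2)

    def test_underdetermined_fit_absent(self, cfg):
        tiny = pupil.RegionCandidate(
            coords=np.array([[5, 5], [5, 6]]), area=2.0, perimeter=2.0,
            circularity=1.0, centroid=(5.0, 5.5),
        )
        fit, _ = pupil.reconnect_and_fit([tiny], cfg)
        assert fit is None


class TestMeasureFrame:
    def test_clean_frame(self, cfg):
        frame, _ = render_pupil(24)
        fit = pupil.measure_pupil_frame(frame, cfg)
        assert fit.valid
        assert fit.diameter == pytest.approx(24, abs=1)

    def test_uniform_frame_invalid_not_raising(self, cfg):
        fit = pupil.measure_pupil_frame(frame8(np.full((240, 320), 128)), cfg)
        assert not fit.valid and fit.diameter is None and fit.ellipse is None

    def test_translation_invariance(self, cfg):
        base = pupil.measure_pupil_frame(render_pupil(24)[0], cfg)
        moved = pupil.measure_pupil_frame(
            render_pupil(24, center=(170.0, 113.0))[0], cfg
        )
        assert abs(moved.diameter - base.diameter) <= 1.0

    def test_monotone_in_rendered_minor_axis(self, cfg):
        diameters = [
            pupil.measure_pupil_frame(render_pupil(m)[0], cfg).diameter
            for m in range(10, 61, 10)
        ]
        assert all(b > a for a, b in zip(diameters, diameters[1:]))

    def test_intensity_offset_invariance(self, cfg):
        frame, _ = render_pupil(24)
        shifted = pupil.GrayFrame(
            np.clip(frame.pixels.astype(int) + 20, 0, 255).astype(np.uint8)
        )
        d0 = pupil.measure_pupil_frame(frame, cfg).diameter
        d1 = pupil.measure_pupil_frame(shifted, cfg).diameter
        assert abs(d1 - d0) <= 1.0


class TestLowpassAndTimeseries:
    def test_dc_preserved(self):
        out = pupil.lowpass_filter(np.full(600, 25.0), 120.0)
        assert np.abs(out - 25.0).max() < 25 * 1e-6

    def test_10hz_attenuated_by_1000x(self):
        # steady-state response, away from the filter's edge transients
        fs = 120.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        out = pupil.lowpass_filter(x, fs)
        mid = slice(len(t) // 3, 2 * len(t) // 3)
        assert np.abs(out[mid]).max() <= 1e-3

    def test_zero_phase_no_peak_shift(self):
        pulse = signal.windows.gaussian(401, std=25)
        out = pupil.lowpass_filter(pulse, 120.0)
        assert int(np.argmax(out)) == int(np.argmax(pulse))

    def test_causal_mode_delays_peak(self):
        pulse = signal.windows.gaussian(401, std=25)
        out = pupil.lowpass_filter(pulse, 120.0, zero_phase=False)
        assert int(np.argmax(out)) > int(np.argmax(pulse))

    def test_constant_sequence_constant_output(self, cfg):
        frame, _ = render_pupil(24)
        trace = pupil.pupil_timeseries([frame] * 40, cfg)
        d = trace.diameter_px[0]
        assert np.abs(trace.diameter_filtered_px - d).max() < 0.01

    def test_invalid_frame_interpolated(self, cfg):
        good, _ = render_pupil(24)
        blank = frame8(np.full((240, 320), 128))
        frames = [good] * 5 + [blank] + [good] * 5
        trace = pupil.pupil_timeseries(frames, cfg)
        assert not trace.valid[5] and trace.interpolated[5]
        assert trace.diameter_px[5] == pytest.approx(trace.diameter_px[4], abs=1e-9)

    def test_long_gap_left_missing(self, cfg):
        good, _ = render_pupil(24)
        blank = frame8(np.full((240, 320), 128))
        # 15 invalid frames at 20 fps = 0.75 s > max_gap 0.5 s
        frames = [good] * 5 + [blank] * 15 + [good] * 5
        trace = pupil.pupil_timeseries(frames, cfg)
        assert np.isnan(trace.diameter_px[5:20]).all()

    def test_all_invalid_errors(self, cfg):
        blank = frame8(np.full((240, 320), 128))
        with pytest.raises(ValueError):
            pupil.pupil_timeseries([blank] * 4, cfg)

    def test_low_sampling_rate_skips_filter_with_warning(self, cfg):
        frame, _ = render_pupil(24)
        slow = pupil.PupilConfig(sampling_rate=1.5)
        with pytest.warns(UserWarning):
            trace = pupil.pupil_timeseries([frame] * 6, slow)
        assert np.allclose(trace.diameter_filtered_px, trace.diameter_px)
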