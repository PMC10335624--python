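"""Segmentation and phase-space imaging: geometry, invariances, features."""

import numpy as np
import pytest

from psrscreen import (
    EcgRecording,
    delay_embed,
    psr_features,
    rasterize_psr,
    segment_recording,
    segment_to_image,
)
from psrscreen.errors import ParameterError
from psrscreen.psr import EcgSegment, save_png, save_txt, write_image_batch


def sine_segment(amp=1.0, freq=5.0, fs=500.0, duration=10.0, phase=0.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t + phase)


def brute_force_raster(points, resolution, lo, hi):
    """Independent per-point binning used as the rasteriser oracle."""
    counts = np.zeros((resolution, resolution))
    for x, y in points:
        col = min(max(int(np.floor((x - lo) / (hi - lo) * resolution)), 0), resolution - 1)
        row = min(max(int(np.floor((y - lo) / (hi - lo) * resolution)), 0), resolution - 1)
        counts[row, col] += 1
    return counts


class TestSegmentation:
    def test_segment_count_arithmetic(self):
        rec = EcgRecording(np.zeros((2, 86_400 * 50)), fs=50)
        segs = segment_recording(rec)
        assert all(len(v) == 8_640 for v in segs.values())

    def test_table_vector_total_at_study_rate(self):
        rec = EcgRecording(
            np.zeros((1, 8_610 * 10 * 500)), fs=500, vector_labels=("alternate",)
        )
        assert len(segment_recording(rec)["alternate"]) == 8_610

    def test_trailing_partial_segment_dropped(self):
        rec = EcgRecording(np.zeros((2, int(25 * 500))), fs=500)
        segs = segment_recording(rec)["primary"]
        assert len(segs) == 2
        assert segs[0].samples.size == 5000

    def test_segments_contiguous_and_nonoverlapping(self):
        x = np.arange(2 * 30 * 500, dtype=float).reshape(2, -1)
        rec = EcgRecording(x, fs=500)
        segs = segment_recording(rec)["primary"]
        joined = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(joined, x[0])

    def test_short_recording_warns_and_returns_empty(self):
        rec = EcgRecording(np.zeros((2, 100)), fs=500)
        with pytest.warns(UserWarning):
            segs = segment_recording(rec)
        assert segs["primary"] == []


class TestDelayEmbed:
    def test_point_count_and_convention(self):
        x = np.arange(10.0)
        pts = delay_embed(x, 3)
        assert pts.shape == (7, 2)
        # x-coordinate is the current sample, y the delayed copy
        np.testing.assert_array_equal(pts[0], [3.0, 0.0])
        np.testing.assert_array_equal(pts[-1], [9.0, 6.0])

    def test_constant_signal_degenerates_to_one_point(self):
        pts = delay_embed(np.full(100, 2.5), 5)
        assert np.all(pts == 2.5)

    def test_sine_at_quarter_period_traces_a_circle(self):
        amp, freq, fs = 1.3, 5.0, 500.0
        lag = int(fs / freq / 4)  # quarter period
        pts = delay_embed(sine_segment(amp, freq, fs), lag)
        radii = np.hypot(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(radii, amp, rtol=1e-6)

    def test_lag_bounds(self):
        with pytest.raises(ParameterError):
            delay_embed(np.zeros(10), 10)
        with pytest.raises(ParameterError):
            delay_embed(np.zeros(10), 0)


class TestRasterize:
    def test_resolution_and_intensity_range(self):
        pts = delay_embed(sine_segment(), 25)
        img = rasterize_psr(pts, resolution=32)
        assert img.pixels.shape == (32, 32)
        assert img.pixels.min() >= 0 and img.pixels.max() == 1.0

    def test_diagonal_points_light_only_diagonal(self):
        v = np.linspace(0.0, 1.0, 200)
        img = rasterize_psr(np.column_stack([v, v]), resolution=16, norm_pct=(0, 100))
        lit = np.argwhere(img.pixels > 0)
        assert np.all(lit[:, 0] == lit[:, 1])

    def test_sine_ring_has_dark_centre(self):
        pts = delay_embed(sine_segment(amp=2.0), 25)
        img = rasterize_psr(pts)
        c = img.resolution // 2
        assert img.pixels[c - 2:c + 2, c - 2:c + 2].sum() == 0.0
        assert psr_features(img)["box_count"] > 0

    def test_constant_signal_lights_single_centre_pixel(self):
        pts = delay_embed(np.full(5000, 0.7), 10)
        img = rasterize_psr(pts)
        lit = np.argwhere(img.pixels > 0)
        assert lit.shape == (1, 2)
        assert tuple(lit[0]) == (16, 16)

    def test_amplitude_scale_invariance(self):
        x = sine_segment(amp=0.9, freq=7.0) + 0.3 * sine_segment(amp=1, freq=13.0)
        for alpha in (0.25, 3.0, 117.0):
            a = rasterize_psr(delay_embed(x, 10))
            b = rasterize_psr(delay_embed(alpha * x, 10))
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_matches_brute_force_binning_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(500, 2))
        lo, hi = np.percentile(pts, (1.0, 99.0))
        expected = brute_force_raster(pts, 32, lo, hi)
        img = rasterize_psr(pts, resolution=32)
        np.testing.assert_allclose(img.pixels, expected / expected.max())
        # total visit count is conserved before normalisation
        assert expected.sum() == len(pts)

    def test_empty_point_set_rejected(self):
        with pytest.raises(ParameterError):
            rasterize_psr(np.empty((0, 2)))

    def test_time_shift_by_whole_periods_is_invariant(self):
        # two windows of the same periodic signal, offset by 3 periods
        freq, fs = 5.0, 500.0
        long = sine_segment(freq=freq, fs=fs, duration=12.0)
        period = int(fs / freq)
        a = segment_to_image(EcgSegment(long[:5000], fs=fs))
        b = segment_to_image(EcgSegment(long[3 * period:3 * period + 5000], fs=fs))
        np.testing.assert_allclose(a.pixels, b.pixels)


class TestFeaturesAndExport:
    def test_feature_definitions(self):
        pix = np.zeros((32, 32))
        pix[0, 0] = 1.0
        pix[5, 7] = 0.5
        from psrscreen.psr import PsrImage
        f = psr_features(PsrImage(pix, lag_s=0.02, norm_bounds=(0, 1)))
        assert f["box_count"] == 2
        assert f["occupied_area_fraction"] == 2 / 32**2
        assert f["row_sums"].sum() == pytest.approx(1.5)
        assert f["col_sums"][7] == 0.5

    def test_fully_lit_and_empty_extremes(self):
        from psrscreen.psr import PsrImage
        full = psr_features(PsrImage(np.ones((8, 8)), 0.02, (0, 1)))
        assert full["occupied_area_fraction"] == 1.0
        empty = psr_features(PsrImage(np.zeros((8, 8)), 0.02, (0, 1)))
        assert empty["box_count"] == 0

    def test_txt_and_png_export(self, tmp_path):
        img = segment_to_image(EcgSegment(sine_segment(), fs=500))
        save_txt(img, tmp_path / "img.txt")
        np.testing.assert_allclose(np.loadtxt(tmp_path / "img.txt"), img.pixels, atol=1e-6)
        save_png(img, tmp_path / "img.png")
        from PIL import Image
        assert Image.open(tmp_path / "img.png").size == (32, 32)

    def test_batch_writer_naming(self, tmp_path):
        segs = [
            EcgSegment(sine_segment(), fs=500, vector_label="primary",
                       segment_index=k, patient_id="p01")
            for k in range(3)
        ]
        paths = write_image_batch(segs, tmp_path, fmt="txt")
        assert [p.name for p in paths] == [
            "p01_primary_00000.txt", "p01_primary_00001.txt", "p01_primary_00002.txt",
        ]
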