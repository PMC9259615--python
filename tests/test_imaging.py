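"""Segmentation, trace extraction, size statistics and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penosome import imaging as im
from penosome.errors import ConfigError
from penosome.synth import sample_proteinosome_population, synthesize_image_stack
from penosome.traces import KineticTrace, TraceSet

PX = 0.5  # um per pixel used throughout


def _traceset(intensities, n_frames=1):
    t = np.arange(n_frames) * 3.0
    traces = [KineticTrace(t=t, A=np.full(n_frames, float(v)),
                           compartment_id=f"c{i}", population="p")
              for i, v in enumerate(intensities)]
    return TraceSet(traces=traces, time_grid=t)


def _disk_frame(diam_um, value=100.0, shape=(300, 300), center=None):
    img = np.zeros(shape)
    cy, cx = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= (diam_um / 2 / PX) ** 2] = value
    return img


class TestSegmentation:
    def test_six_clean_disks_recovered(self):
        ts = _traceset([100.0] * 6)
        stack, truth = synthesize_image_stack([10.0] * 6, None, ts, PX,
                                              (300, 300), 0.0, seed=1)
        recs = im.segment_proteinosomes(stack[0], PX)
        assert len(recs) == 6
        for rec in recs:
            assert rec.circularity >= 0.9
            assert 2 * rec.radius == pytest.approx(20.0, abs=PX)
        # centroids within one pixel of the rendered truth
        got = sorted((r.centroid for r in recs))
        want = sorted(zip(truth[truth.frame == 0].x_um,
                          truth[truth.frame == 0].y_um))
        for (gx, gy), (wx, wy) in zip(got, want):
            assert np.hypot(gx - wx, gy - wy) <= PX

    def test_oversize_disk_filtered(self):
        recs = im.segment_proteinosomes(_disk_frame(40.0), PX)
        assert recs == []

    def test_undersize_disk_filtered(self):
        recs = im.segment_proteinosomes(_disk_frame(10.0), PX)
        assert recs == []

    def test_elongated_ellipse_fails_circularity(self):
        img = np.zeros((300, 300))
        yy, xx = np.mgrid[0:300, 0:300]
        a = 10.0 * np.sqrt(3.0) / PX
        b = 10.0 / np.sqrt(3.0) / PX
        img[((xx - 150) / a) ** 2 + ((yy - 150) / b) ** 2 <= 1.0] = 100.0
        assert im.segment_proteinosomes(img, PX) == []

    def test_otsu_segmentation_is_scale_invariant(self):
        ts = _traceset([100.0] * 4)
        stack, _ = synthesize_image_stack([10.0] * 4, None, ts, PX,
                                          (300, 300), 2.0, seed=2)
        a = im.segment_proteinosomes(stack[0], PX)
        b = im.segment_proteinosomes(stack[0] * 7.3, PX)
        assert len(a) == len(b) == 4
        for ra, rb in zip(a, b):
            assert ra.centroid == pytest.approx(rb.centroid)
            assert ra.radius == pytest.approx(rb.radius)

    def test_filters_are_sound(self):
        """No returned record may violate the ranges actually passed."""
        rng = np.random.default_rng(9)
        ts = _traceset([100.0] * 5)
        radii = [5.0, 8.0, 10.0, 12.0, 20.0]
        stack, _ = synthesize_image_stack(radii, None, ts, PX, (400, 400),
                                          3.0, seed=9)
        circ_rng, diam_rng = (0.8, 1.0), (15.0, 22.0)
        for rec in im.segment_proteinosomes(stack[0], PX,
                                            circularity_range=circ_rng,
                                            diameter_range_um=diam_rng):
            assert circ_rng[0] <= rec.circularity <= circ_rng[1]
            assert diam_rng[0] <= 2 * rec.radius <= diam_rng[1]

    def test_constant_frame_yields_nothing(self):
        assert im.segment_proteinosomes(np.zeros((50, 50)), PX) == []

    def test_bad_pixel_size_rejected(self):
        with pytest.raises(ConfigError):
            im.segment_proteinosomes(np.zeros((10, 10)), 0.0)


class TestExtraction:
    def test_uniform_disk_reads_back_exactly(self):
        stack = np.stack([_disk_frame(20.0, 100.0)] * 5)
        yy, xx = np.mgrid[0:300, 0:300]
        mask = (xx - 150) ** 2 + (yy - 150) ** 2 <= (8.0 / PX) ** 2  # interior
        rec = im.ProteinosomeRecord(id=0, centroid=(75.0, 75.0), radius=10.0,
                                    area=np.pi * 100, circularity=1.0,
                                    mask=mask)
        traces = im.extract_traces(stack, [rec])
        np.testing.assert_array_equal(traces[0].A, 100.0)

    def test_intensity_ramp_reads_back(self):
        frames = [_disk_frame(20.0, v) for v in (0.0, 50.0, 100.0)]
        yy, xx = np.mgrid[0:300, 0:300]
        mask = (xx - 150) ** 2 + (yy - 150) ** 2 <= (8.0 / PX) ** 2
        rec = im.ProteinosomeRecord(0, (75.0, 75.0), 10.0, np.pi * 100, 1.0,
                                    mask=mask)
        traces = im.extract_traces(np.stack(frames), [rec])
        np.testing.assert_allclose(traces[0].A, [0.0, 50.0, 100.0])

    def test_round_trip_through_noisy_rendering(self):
        """Extracted traces track the generating intensities within the
        noise-over-sqrt(area) bound."""
        rng_vals = np.linspace(80, 200, 4)
        t = np.arange(4) * 3.0
        traces_in = [KineticTrace(t=t, A=rng_vals, compartment_id="c0",
                                  population="p")]
        ts = TraceSet(traces=traces_in, time_grid=t)
        noise = 5.0
        stack, _ = synthesize_image_stack([10.0], [(75.0, 75.0)], ts, PX,
                                          (300, 300), noise, seed=4)
        # with the rendering mask the only error is averaged read noise
        yy, xx = np.mgrid[0:300, 0:300]
        true_mask = ((xx + 0.5) * PX - 75.0) ** 2 + \
                    ((yy + 0.5) * PX - 75.0) ** 2 <= 10.0 ** 2
        rec = im.ProteinosomeRecord(0, (75.0, 75.0), 10.0, np.pi * 100, 1.0,
                                    mask=true_mask)
        out = im.extract_traces(stack, [rec])[0]
        bound = 3.0 * noise / np.sqrt(true_mask.sum())
        assert np.all(np.abs(out.A - rng_vals) < bound)
        # the segmented mask admits ~1 px of boundary background on top
        recs = im.segment_proteinosomes(stack[0], PX)
        assert len(recs) == 1
        seg = im.extract_traces(stack, recs)[0]
        assert np.all(np.abs(seg.A - rng_vals) / rng_vals < 0.03)

    def test_empty_mask_skipped(self):
        rec = im.ProteinosomeRecord(0, (0, 0), 1.0, 3.14, 1.0,
                                    mask=np.zeros((10, 10), bool))
        assert im.extract_traces(np.zeros((2, 10, 10)), [rec]) == []


class TestSizeStatistics:
    def test_degenerate_sample(self):
        s = im.size_statistics([10.0, 10.0, 10.0])
        assert (s.mean_radius, s.sd_radius, s.rsd) == (10.0, 0.0, 0.0)

    def test_hand_computed_sample_sd(self):
        s = im.size_statistics([12.0, 24.0, 36.0])
        assert s.mean_radius == pytest.approx(24.0)
        assert s.sd_radius == pytest.approx(12.0)
        assert s.rsd == pytest.approx(50.0)

    def test_polydisperse_summary_rounds_to_48(self):
        # bulk-emulsion population summary: 24.0 +/- 11.4 um
        assert round(100.0 * 11.4 / 24.0) == 48

    def test_single_radius_has_no_spread_stats(self):
        s = im.size_statistics([9.0])
        assert s.sd_radius is None and s.rsd is None

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(1.0, 100.0), min_size=2, max_size=50))
    def test_matches_numpy_oracle(self, radii):
        s = im.size_statistics(radii)
        r = np.asarray(radii)
        assert s.mean_radius == pytest.approx(r.mean())
        assert s.sd_radius == pytest.approx(r.std(ddof=1))

    def test_converges_to_generator_moments(self):
        r = sample_proteinosome_population(20_000, 12.1, 14.0, "normal", seed=8)
        s = im.size_statistics(r)
        assert s.mean_radius == pytest.approx(12.1, rel=0.01)
        assert s.rsd == pytest.approx(14.0, abs=0.5)


class TestCalibration:
    def test_exact_line(self):
        c = im.fit_calibration([10, 20, 40], [100.0, 200.0, 400.0])
        assert c.slope == pytest.approx(10.0)
        assert c.intercept == pytest.approx(0.0, abs=1e-9)
        assert c.r_squared == pytest.approx(1.0)
        assert im.estimate_proteinosome_count(250.0, c) == pytest.approx(25.0)

    def test_inverse_examples(self):
        c = im.CalibrationCurve(slope=10.0, intercept=0.0, r_squared=1.0)
        assert im.estimate_proteinosome_count(120.0, c) == pytest.approx(12.0)
        c2 = im.CalibrationCurve(slope=5.0, intercept=30.0, r_squared=1.0)
        assert im.estimate_proteinosome_count(30.0, c2) == 0.0   # at intercept
        assert im.estimate_proteinosome_count(10.0, c2) == 0.0   # clamped

    def test_noisy_line_within_three_se(self):
        rng = np.random.default_rng(5)
        counts = np.arange(5, 105, 10)
        fluo = 12.0 * counts + 40.0 + rng.normal(0, 15.0, counts.size)
        c = im.fit_calibration(counts, fluo)
        se = np.sqrt(np.sum((fluo - c.slope * counts - c.intercept) ** 2)
                     / (counts.size - 2) / np.sum((counts - counts.mean()) ** 2))
        assert abs(c.slope - 12.0) < 3 * se

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ConfigError):
            im.fit_calibration([5, 5, 5], [1.0, 2.0, 3.0])

    def test_invalid_curve_rejected(self):
        bad = im.CalibrationCurve(slope=0.0, intercept=0.0, r_squared=0.0)
        with pytest.raises(ConfigError):
            im.estimate_proteinosome_count(10.0, bad)


class TestTemplateConcentration:
    @pytest.mark.parametrize("vol,expected", [
        (0.0, 0.0),
        (0.005, 0.6),       # the reference dispersion density
        (0.01358, 1.6296),  # the top of the density range
    ])
    def test_volume_fraction_arithmetic(self, vol, expected):
        got = im.total_template_concentration(vol, 1.0, 0.12)
        assert got == pytest.approx(expected, abs=5e-3)

    def test_overfull_sample_rejected(self):
        with pytest.raises(ConfigError):
            im.total_template_concentration(2.0, 1.0)
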