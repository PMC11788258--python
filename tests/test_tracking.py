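"""Tracking: Otsu thresholding, strip segmentation, centroids, MAE, geometry."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbtrack import recon, scene, tracking


def make_frame(wet_map, coverage=None, spacing=0.5, timestamp=0.0, frame_index=0):
    wet_map = np.asarray(wet_map, float)
    ny, nx = wet_map.shape
    grid = recon.GridSpec(((nx - 1) * spacing, (ny - 1) * spacing), spacing)
    cov = np.ones_like(wet_map, bool) if coverage is None else coverage
    return recon.FrameImage(wet_map, cov, grid, timestamp, frame_index)


def disk_image(ny=101, nx=181, cx=90, cy=50, r=30, bg=100.0, contrast=20.0, noise=0.0, seed=0):
    yy, xx = np.mgrid[0:ny, 0:nx]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img = np.full((ny, nx), bg)
    img[disk] += contrast
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, img.shape)
    return img, disk


def otsu_oracle(values):
    """Exhaustive search over all candidate thresholds minimising the
    weighted within-class variance; returns the boolean foreground."""
    v = np.sort(np.asarray(values, float))
    best, best_thr = np.inf, None
    for k in range(1, v.size):
        lo, hi = v[:k], v[k:]
        if lo[-1] == hi[0]:
            continue
        wcv = lo.size * lo.var() + hi.size * hi.var()
        if wcv < best:
            best, best_thr = wcv, 0.5 * (lo[-1] + hi[0])
    return np.asarray(values) > best_thr


class TestOtsu:
    def test_two_level_input_separates_exactly(self):
        vals = np.array([0.0] * 100 + [100.0] * 100)
        thr = tracking.otsu_threshold(vals)
        assert 0.0 < thr < 100.0
        assert np.array_equal(vals > thr, vals == 100.0)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(tracking.DegenerateStripError):
            tracking.otsu_threshold(np.full(50, 7.0))

    def test_bimodal_gaussians_low_misclassification(self):
        rng = np.random.default_rng(123)
        a = rng.normal(10, 5, 10_000)
        b = rng.normal(200, 5, 10_000)
        thr = tracking.otsu_threshold(np.concatenate([a, b]))
        wrong = np.sum(a > thr) + np.sum(b <= thr)
        assert wrong / 20_000 < 0.001

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_oracle_on_separated_inputs(self, seed):
        rng = np.random.default_rng(seed)
        lo = rng.integers(0, 40, rng.integers(5, 30))
        hi = rng.integers(160, 200, rng.integers(5, 30))
        vals = np.concatenate([lo, hi]).astype(float)
        thr = tracking.otsu_threshold(vals)
        assert np.array_equal(vals > thr, otsu_oracle(vals))

    def test_matches_skimage_classification(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(50, 8, 500), rng.normal(140, 12, 300)])
        ours = vals > tracking.otsu_threshold(vals)
        theirs = vals > threshold_otsu(vals, nbins=256)
        # conventions differ by at most half a histogram bin
        assert np.mean(ours == theirs) > 0.995


class TestSegmentInsert:
    def test_noisy_disk_dice_above_090(self):
        img, disk = disk_image(noise=1.0)
        mask = tracking.segment_insert(make_frame(img))
        dice = 2 * np.sum(mask & disk) / (mask.sum() + disk.sum())
        assert dice > 0.9

    def test_strip_thresholds_follow_background_gradient(self):
        """With a strip-wise background staircase, per-strip thresholds
        strictly increase with the local background level."""
        ny, nx = 110, 181
        img = np.empty((ny, nx))
        cfg = tracking.TrackerConfig(n_strips=11)
        bounds = tracking.strip_bounds(ny, 11)
        for s in range(11):
            img[bounds[s] : bounds[s + 1]] = 100.0 + 5.0 * s
        # a vertical high-WET bar crossing every strip
        img[:, 85:96] += 25.0
        thresholds = tracking.strip_thresholds(make_frame(img), cfg)
        assert all(t is not None for t in thresholds)
        assert np.all(np.diff(thresholds) > 0)

    def test_all_masked_frame_raises_insert_not_found(self):
        img, _ = disk_image()
        frame = make_frame(img, coverage=np.zeros_like(img, bool))
        with pytest.raises(tracking.InsertNotFoundError):
            tracking.segment_insert(frame)

    def test_largest_component_selected(self):
        img, disk = disk_image(noise=0.5)
        img[5:10, 5:12] += 30.0  # a small bright speck far from the disk
        mask = tracking.segment_insert(make_frame(img))
        assert not mask[5:10, 5:12].any()
        assert (mask & disk).sum() > 0.8 * disk.sum()


class TestCentroidOffset:
    def test_centered_disk_reads_zero(self):
        img, _ = disk_image()
        frame = make_frame(img)
        mask = tracking.segment_insert(frame)
        assert tracking.centroid_offset(mask, frame) == pytest.approx(0.0, abs=0.125)

    def test_translation_equivariance(self):
        frames = []
        for cx in (90, 104):  # 14 px = 7 mm at 0.5 mm spacing
            img, _ = disk_image(cx=cx, noise=0.2)
            frames.append(make_frame(img))
        offs = [tracking.centroid_offset(tracking.segment_insert(f), f) for f in frames]
        assert offs[1] - offs[0] == pytest.approx(7.0, abs=0.25)

    def test_two_pixel_mask_arithmetic(self):
        img = np.zeros((3, 5))
        frame = make_frame(img, spacing=1.0)
        mask = np.zeros((3, 5), bool)
        # grid x coordinates are -2..2 mm; pixels at x = 1 and 3 mm -> indices 3, 4...
        xs = frame.grid.x_coords()
        mask[1, np.searchsorted(xs, 1.0)] = True
        mask[1, np.searchsorted(xs, 2.0)] = True
        assert tracking.centroid_offset(mask, frame) == pytest.approx(1.5)

    def test_empty_mask_rejected(self):
        img, _ = disk_image()
        with pytest.raises(ValueError):
            tracking.centroid_offset(np.zeros_like(img, bool), make_frame(img))


class TestExpectedOffset:
    def test_peak_to_peak_recentring(self):
        m = scene.MotionModel(20.0, 24.0)
        assert tracking.expected_offset(0.0, m) == pytest.approx(-10.0)
        t = np.linspace(0, 24, 241)
        offs = np.array([tracking.expected_offset(float(ti), m) for ti in t])
        assert offs.min() >= -10.0 - 1e-9 and offs.max() <= 10.0 + 1e-9
        assert np.trapezoid(offs, t) / 24.0 == pytest.approx(0.0, abs=1e-6)

    def test_zero_amplitude_is_zero_everywhere(self):
        m = scene.MotionModel(0.0, 24.0)
        assert tracking.expected_offset(13.7, m) == 0.0


class TestEvaluateTracking:
    def _motion_frames(self, errors_mm):
        """Synthetic disk frames whose centroids differ from the programmed
        positions by the requested per-frame errors."""
        motion = scene.MotionModel(10.0, 24.0)
        frames = []
        for i, err in enumerate(errors_mm):
            t = 3.0 * i
            offset = tracking.expected_offset(t, motion) + err
            img, _ = disk_image(cx=90 + int(round(offset / 0.5)))
            frames.append(make_frame(img, timestamp=t, frame_index=i))
        return frames, motion

    def test_exact_tracking_gives_zero_mae(self):
        frames, motion = self._motion_frames([0.0, 0.0, 0.0])
        res = tracking.evaluate_tracking(frames, motion)
        assert res.mae == pytest.approx(0.0, abs=0.26)  # half-pixel rasterisation
        assert res.sigma == pytest.approx(0.0, abs=0.26)

    def test_mae_is_mean_of_absolute_errors(self):
        frames, motion = self._motion_frames([1.0, -2.0, 3.0])
        res = tracking.evaluate_tracking(frames, motion)
        assert res.mae == pytest.approx(2.0, abs=0.3)
        assert len(res.per_frame) == 3
        assert res.mae == pytest.approx(res.per_frame["abs_error_mm"].mean())

    def test_untrackable_frames_are_excluded_and_reported(self):
        frames, motion = self._motion_frames([0.0, 0.0])
        img = np.full_like(frames[0].wet_map, 100.0)
        frames.append(make_frame(img, coverage=np.zeros_like(img, bool), timestamp=6.0, frame_index=2))
        res = tracking.evaluate_tracking(frames, motion)
        assert res.excluded_frames == [2]
        assert len(res.per_frame) == 2

    def test_no_trackable_frame_raises(self):
        img = np.full((20, 30), 5.0)
        frame = make_frame(img, coverage=np.zeros_like(img, bool))
        with pytest.raises(tracking.InsertNotFoundError):
            tracking.evaluate_tracking([frame], scene.MotionModel(10, 24))


class TestMaxBeamsCrossing:
    def test_ten_mm_tumor_at_five_mm_spacing(self):
        """At 5 mm spacing at most four beams cross a 10 mm tumor projection."""
        assert tracking.max_beams_crossing(10.0, 5.0) == 4

    def test_spacing_larger_than_diameter(self):
        assert tracking.max_beams_crossing(5.0, 10.0) == 1

    def test_matches_independent_loop_oracle(self):
        """Independent coarse re-implementation (plain loops) agrees."""
        def oracle(diameter, spacing, res=0.05):
            r = diameter / 2
            m = int(np.ceil(r / spacing)) + 1
            nodes = [(i * spacing, j * spacing) for i in range(-m, m + 1) for j in range(-m, m + 1)]
            best = 0
            steps = int(spacing / res)
            for a in range(steps):
                for b in range(steps):
                    dx, dy = a * res, b * res
                    c = sum((nx + dx) ** 2 + (ny + dy) ** 2 < r * r - 1e-12 for nx, ny in nodes)
                    best = max(best, c)
            return best

        for d, s in [(30.0, 5.0), (12.0, 5.0)]:
            assert tracking.max_beams_crossing(d, s, resolution=0.05) == oracle(d, s)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tracking.max_beams_crossing(0.0, 5.0)
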