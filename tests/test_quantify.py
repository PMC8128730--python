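"""Scar quantification: rasterization, thresholds, masks and % LV burden."""

import numpy as np
import pytest

from lgequant import (
    ContourSet,
    DenoiseConfig,
    GeometryError,
    ImageStack,
    ROI,
    UndefinedMetricError,
    apply_nr,
    apply_threshold,
    quantify,
    rasterize_myocardium,
    sample_noise,
    scar_percent,
    threshold_fwhm,
    threshold_ksd,
)
from lgequant.quantify import rasterize_polygon


def _circle(center, radius, n=90):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)])


def _point_in_polygon(point, verts):
    """Even-odd ray casting, independent of shapely."""
    r, c = point
    inside = False
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_cross = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
            if c < c_cross:
                inside = not inside
    return inside


class TestRasterize:
    def test_annulus_matches_bruteforce_center_test(self):
        contours = ContourSet({0: (_circle((40.2, 39.7), 25.3), _circle((40.2, 39.7), 14.1))})
        mask = rasterize_myocardium(contours, (1, 80, 80))
        count = sum(
            1
            for r in range(80)
            for c in range(80)
            if 14.1**2 < (r - 40.2) ** 2 + (c - 39.7) ** 2 < 25.3**2
        )
        assert int(mask.sum()) == count

    def test_random_polygons_match_ray_casting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            # random convex polygon (hull of random points), vertices off-grid
            pts = rng.uniform(2, 30, (12, 2))
            from scipy.spatial import ConvexHull

            hull = pts[ConvexHull(pts).vertices]
            mask = rasterize_polygon(hull, (32, 32))
            for r in range(32):
                for c in range(32):
                    assert mask[r, c] == _point_in_polygon((r, c), hull)

    def test_equal_contours_give_empty_slice(self):
        contours = ContourSet({0: (_circle((20, 20), 10), _circle((20, 20), 9.999))})
        mask = rasterize_myocardium(contours, (1, 40, 40))
        assert mask.sum() == 0

    def test_translation_equivariance(self):
        epi, endo = _circle((20.3, 20.3), 12.2), _circle((20.3, 20.3), 7.4)
        base = rasterize_myocardium(ContourSet({0: (epi, endo)}), (1, 64, 64))
        shifted = rasterize_myocardium(
            ContourSet({0: (epi + [5, 9], endo + [5, 9])}), (1, 64, 64)
        )
        assert np.array_equal(np.roll(base, (5, 9), axis=(1, 2)), shifted)

    def test_crossed_polygons_rejected(self):
        bow_tie = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0]])
        with pytest.raises(GeometryError):
            ContourSet({0: (bow_tie, _circle((5, 5), 1))})

    def test_endo_outside_epi_rejected(self):
        with pytest.raises(GeometryError):
            ContourSet({0: (_circle((20, 20), 5), _circle((20, 20), 8))})


class TestThresholds:
    def test_ksd_formula(self):
        vals = np.array([40.0, 60.0])  # mean 50, sd sqrt(200)
        img = ImageStack(voxels=vals.reshape(1, 1, 2))
        roi = ROI(0, np.array([[0, 0], [0, 1]]))
        sd = vals.std(ddof=1)
        assert threshold_ksd(img, roi, 2) == pytest.approx(50 + 2 * sd)
        assert threshold_ksd(img, roi, 6) == pytest.approx(50 + 6 * sd)

    def test_ksd_degenerate_zero_sd(self, flat_stack):
        roi = ROI.from_circle(0, (32, 32), 4)
        assert threshold_ksd(flat_stack, roi, 4) == 100.0

    def test_fwhm_half_max(self):
        img = ImageStack(voxels=np.array([[[10.0, 320.0, 5.0]]]))
        roi = ROI(0, np.array([[0, 0], [0, 1], [0, 2]]))
        assert threshold_fwhm(img, roi) == 160.0

    def test_fwhm_scales_with_intensity(self, default_case):
        stack, truth = default_case
        t1 = threshold_fwhm(stack, truth.scar_roi)
        t2 = threshold_fwhm(stack.with_voxels(stack.voxels * 3.0), truth.scar_roi)
        assert t2 == pytest.approx(3.0 * t1, rel=1e-12)

    def test_fwhm_all_zero_roi_rejected(self):
        img = ImageStack(voxels=np.zeros((1, 4, 4)))
        with pytest.raises(UndefinedMetricError):
            threshold_fwhm(img, ROI(0, np.array([[0, 0], [0, 1]])))

    def test_ksd_threshold_decreases_with_nr_in_expectation(self, default_case):
        # the core mechanism: denoising shrinks the remote-ROI SD, hence the
        # kSD threshold falls as the NR level rises (averaged over seeds)
        stack, truth = default_case
        nr_levels = (0.0, 0.25, 0.5, 0.75, 1.0)
        mean_thr = np.zeros(len(nr_levels))
        for seed in range(30):
            noise = sample_noise(stack.voxels.shape, 12.0, seed=seed)
            for j, nr in enumerate(nr_levels):
                img = apply_nr(stack, noise, DenoiseConfig(nr))
                mean_thr[j] += threshold_ksd(img, truth.remote_roi, 4)
        mean_thr /= 30
        assert all(a > b for a, b in zip(mean_thr, mean_thr[1:]))


class TestApplyThresholdAndPercent:
    def test_threshold_above_max_gives_empty_mask(self, flat_stack):
        myo = np.ones(flat_stack.voxels.shape, bool)
        assert apply_threshold(flat_stack, myo, 101.0).sum() == 0

    def test_threshold_zero_selects_whole_myocardium(self, flat_stack):
        myo = np.zeros(flat_stack.voxels.shape, bool)
        myo[0, 10:20, 10:20] = True
        assert np.array_equal(apply_threshold(flat_stack, myo, 0.0), myo)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(3)
        img = ImageStack(voxels=rng.uniform(0, 10, (1, 16, 16)))
        myo = rng.uniform(size=(1, 16, 16)) < 0.6
        thr = 5.0
        mask = apply_threshold(img, myo, thr)
        for r in range(16):
            for c in range(16):
                expected = myo[0, r, c] and img.voxels[0, r, c] >= thr
                assert mask[0, r, c] == expected

    def test_pixels_exactly_at_threshold_count_as_scar(self):
        img = ImageStack(voxels=np.array([[[5.0, 4.999]]]))
        myo = np.ones((1, 1, 2), bool)
        assert apply_threshold(img, myo, 5.0).tolist() == [[[True, False]]]

    def test_percent_arithmetic(self, flat_stack):
        myo = np.zeros(flat_stack.voxels.shape, bool)
        myo[0, :25, :40] = True  # 1000 pixels
        scar = np.zeros_like(myo)
        scar[0, :15, :10] = True  # 150 pixels
        assert scar_percent(scar, myo, flat_stack) == pytest.approx(15.0)

    def test_full_scar_is_100_percent(self, flat_stack):
        myo = np.zeros(flat_stack.voxels.shape, bool)
        myo[0, 5:30, 5:30] = True
        assert scar_percent(myo, myo, flat_stack) == 100.0

    def test_multi_slice_weighted_ratio(self):
        img = ImageStack(voxels=np.zeros((3, 8, 8)))
        myo = np.zeros((3, 8, 8), bool)
        scar = np.zeros((3, 8, 8), bool)
        myo[0, :4, :4] = True   # 16
        myo[1, :5, :8] = True   # 40
        myo[2, :1, :4] = True   # 4
        scar[0, :2, :2] = True  # 4
        scar[1, :1, :3] = True  # 3
        # uniform slice geometry: weighted ratio reduces to count ratio
        assert scar_percent(scar, myo, img) == pytest.approx(100.0 * 7 / 60)

    def test_scar_outside_myo_rejected(self, flat_stack):
        myo = np.zeros(flat_stack.voxels.shape, bool)
        myo[0, :4, :4] = True
        scar = np.zeros_like(myo)
        scar[0, 10, 10] = True
        with pytest.raises(ValueError):
            scar_percent(scar, myo, flat_stack)

    def test_empty_myocardium_rejected(self, flat_stack):
        empty = np.zeros(flat_stack.voxels.shape, bool)
        with pytest.raises(UndefinedMetricError):
            scar_percent(empty, empty, flat_stack)


class TestQuantify:
    def test_fwhm_recovers_truth_on_clean_wedge(self, clean_wedge_case):
        stack, truth = clean_wedge_case
        res = quantify(stack, truth, "fwhm")
        assert res.scar_percent_lv == pytest.approx(truth.true_scar_percent, abs=1e-12)

    def test_manual_returns_truth(self, clean_wedge_case):
        stack, truth = clean_wedge_case
        res = quantify(stack, truth, "manual")
        assert res.scar_percent_lv == truth.true_scar_percent
        assert res.threshold is None

    def test_sd_method_ordering_and_mask_nesting(self, default_case):
        stack, truth = default_case
        noise = sample_noise(stack.voxels.shape, 12.0, seed=4)
        img = apply_nr(stack, noise, DenoiseConfig(0.25))
        res = {m: quantify(img, truth, m) for m in ("sd2", "sd4", "sd6")}
        assert res["sd2"].threshold < res["sd4"].threshold < res["sd6"].threshold
        assert (
            res["sd2"].scar_percent_lv
            >= res["sd4"].scar_percent_lv
            >= res["sd6"].scar_percent_lv
        )

    def test_affine_rescale_invariance_of_scar_percent(self, default_case):
        # both kSD and FWHM thresholds transform covariantly under a > 0
        stack, truth = default_case
        noise = sample_noise(stack.voxels.shape, 12.0, seed=5)
        img = apply_nr(stack, noise, DenoiseConfig(0.5))
        scaled = img.with_voxels(img.voxels * 2.5)
        for method in ("sd2", "sd6", "fwhm"):
            a = quantify(img, truth, method)
            b = quantify(scaled, truth, method)
            assert a.scar_percent_lv == pytest.approx(b.scar_percent_lv, abs=1e-12)

    def test_degenerate_flag_on_noiseless_textureless_image(self, clean_wedge_case):
        stack, truth = clean_wedge_case
        res = quantify(stack, truth, "sd4")
        assert res.degenerate
        assert res.threshold == pytest.approx(res.remote_mean)

    def test_unknown_method_rejected(self, clean_wedge_case):
        stack, truth = clean_wedge_case
        with pytest.raises(ValueError):
            quantify(stack, truth, "otsu")

    def test_random_small_instances_match_exhaustive_reference(self):
        # end-to-end oracle on tiny grids: thresholds, masks and percentages
        # recomputed with plain python loops
        rng = np.random.default_rng(11)
        for _ in range(30):
            img = ImageStack(voxels=rng.uniform(0, 100, (2, 24, 24)))
            myo = rng.uniform(size=(2, 24, 24)) < 0.4
            if not myo.any():
                continue
            thr = float(rng.uniform(20, 90))
            mask = apply_threshold(img, myo, thr)
            count = 0
            for s in range(2):
                for r in range(24):
                    for c in range(24):
                        if myo[s, r, c] and img.voxels[s, r, c] >= thr:
                            count += 1
            assert int(mask.sum()) == count
            assert scar_percent(mask, myo, img) == pytest.approx(100.0 * count / myo.sum())
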