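"""Colocalization operations: Pearson, ROI geometry, overlap, FACS subtraction."""

import numpy as np
import pytest

import fluorokit as fk
from fluorokit.coloc import RegionMask


def whole(shape):
    return RegionMask(np.ones(shape, bool), kind="whole_cell")


class TestPearson:
    def test_identical_channels_r_is_one(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (32, 32))
        res = fk.pearson_coloc(img, img, whole((32, 32)))
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_inverted_channel_r_is_minus_one(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (32, 32))
        res = fk.pearson_coloc(img, 200.0 - img, whole((32, 32)))
        assert res.pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_has_near_zero_r(self):
        # null distribution over 100 seeds, 10^4 ROI pixels
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(100, 100))
            b = rng.normal(size=(100, 100))
            rs.append(fk.pearson_coloc(a, b, whole((100, 100))).pearson_r)
        assert np.max(np.abs(rs)) < 0.05

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 50, (40, 40))
        b = a + rng.normal(0, 5, (40, 40))
        roi = whole((40, 40))
        r0 = fk.pearson_coloc(a, b, roi).pearson_r
        r1 = fk.pearson_coloc(3.2 * a + 11.0, 0.5 * b + 100.0, roi).pearson_r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_channel_rejected(self):
        a = np.zeros((16, 16))
        b = np.random.default_rng(0).uniform(size=(16, 16))
        with pytest.raises(ValueError, match="channel A"):
            fk.pearson_coloc(a, b, whole((16, 16)))

    def test_increases_with_coloc_fraction(self):
        means = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            rs = []
            for seed in range(10):
                truth = fk.random_scene_truth(20, (192, 192), seed=seed,
                                              coloc_fraction=frac)
                a, b, _ = fk.make_vesicle_scene(truth, (192, 192))
                rs.append(fk.pearson_coloc(a, b, whole((192, 192))).pearson_r)
            means.append(np.mean(rs))
        assert all(x < y for x, y in zip(means, means[1:]))


class TestLeadingEdgeRoi:
    def test_straight_segment_stadium_area(self):
        # half-integer centerline avoids the odd/even rasterization bias
        roi = fk.leading_edge_roi([(100.5, 50.5), (100.5, 150.5)], width=10,
                                  shape=(200, 210))
        expected = 10 * 100 + np.pi * 25  # rectangle + two half-disk caps
        assert roi.n_pixels == pytest.approx(expected, rel=0.02)

    def test_width_one_is_rasterized_line(self):
        roi = fk.leading_edge_roi([(10, 2), (10, 20)], width=1, shape=(21, 23)).mask
        assert roi[10, 2:21].all()
        assert roi.sum() == 19

    def test_l_shaped_path_matches_distance_oracle(self):
        path = [(30.0, 10.0), (30.0, 40.0), (60.0, 40.0)]
        width = 8
        shape = (80, 60)
        roi = fk.leading_edge_roi(path, width=width, shape=shape)

        def seg_dist(p, a, b):
            p, a, b = map(np.asarray, (p, a, b))
            if np.all(a == b):
                return np.linalg.norm(p - a)
            t = np.clip(np.dot(p - a, b - a) / np.dot(b - a, b - a), 0, 1)
            return np.linalg.norm(p - (a + t * (b - a)))

        oracle = np.zeros(shape, bool)
        for r in range(shape[0]):
            for c in range(shape[1]):
                d = min(seg_dist((r, c), path[i], path[i + 1]) for i in range(2))
                oracle[r, c] = d <= width / 2
        np.testing.assert_array_equal(roi.mask, oracle)

    def test_degenerate_path_rejected(self):
        with pytest.raises(ValueError, match="degenerate|2 "):
            fk.leading_edge_roi([(5, 5), (5, 5)], width=4, shape=(20, 20))


class TestMembraneBand:
    def test_square_band_area_arithmetic(self):
        mask = np.zeros((31, 31), bool)
        mask[5:26, 5:26] = True  # 21x21 square
        band = fk.membrane_band(RegionMask(mask), width=3)
        assert band.n_pixels == 21**2 - 15**2

    def test_zero_width_rejected(self):
        mask = RegionMask(np.ones((10, 10), bool))
        with pytest.raises(ValueError, match=">= 1"):
            fk.membrane_band(mask, width=0)

    def test_thin_cell_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[9:11, 2:18] = True
        with pytest.raises(ValueError, match="thinner"):
            fk.membrane_band(RegionMask(mask), width=3)

    def test_disk_matches_brute_force_erosion_oracle(self):
        rr, cc = np.indices((50, 50))
        mask = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20**2
        band = fk.membrane_band(RegionMask(mask), width=2)
        # oracle: pixel survives erosion iff no complement pixel within distance 2
        inside = np.argwhere(mask)
        outside = np.argwhere(~mask)
        oracle = np.zeros_like(mask)
        for r, c in inside:
            d2 = np.min((outside[:, 0] - r) ** 2 + (outside[:, 1] - c) ** 2)
            oracle[r, c] = d2 <= 4  # within the band if eroded away
        np.testing.assert_array_equal(band.mask, oracle)


class TestIntensityLevels:
    def test_uniform_image_means_equal(self):
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        cell = RegionMask(mask)
        band = fk.membrane_band(cell, width=3)
        res = fk.intensity_levels(np.full((40, 40), 42.0), cell, band)
        assert res.total_mean == res.surface_mean == 42.0

    def test_normalization_against_control(self):
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        cell = RegionMask(mask)
        band = fk.membrane_band(cell, width=3)
        img = np.full((40, 40), 10.0)
        res = fk.intensity_levels(img, cell, band, control_means=(10.0, 10.0))
        assert res.normalized_total == pytest.approx(1.0)
        assert res.normalized_surface == pytest.approx(1.0)

    def test_band_not_subset_rejected(self):
        cell = RegionMask(np.zeros((20, 20), bool))
        cell.mask[5:15, 5:15] = True
        bad = RegionMask(np.ones((20, 20), bool), kind="membrane_band")
        with pytest.raises(ValueError, match="subset"):
            fk.intensity_levels(np.ones((20, 20)), cell, bad)

    def test_matches_masked_mean_oracle_on_random_masks(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, (64, 64))
        cell = rng.random((64, 64)) < 0.6
        band = cell & (rng.random((64, 64)) < 0.3)
        if not band.any():  # pragma: no cover - astronomically unlikely
            band[np.argwhere(cell)[0]] = True
        res = fk.intensity_levels(img, RegionMask(cell), RegionMask(band))
        assert res.total_mean == pytest.approx(img[cell].sum() / cell.sum())
        assert res.surface_mean == pytest.approx(img[band].sum() / band.sum())


class TestVesicleOverlap:
    def _detect_pair(self, frac, seed):
        truth = fk.random_scene_truth(20, (192, 192), seed=seed, coloc_fraction=frac)
        a, b, _ = fk.make_vesicle_scene(truth, (192, 192))
        return fk.detect_vesicles(a), fk.detect_vesicles(b)

    def test_self_overlap_is_one(self):
        va, _ = self._detect_pair(0.5, 0)
        res = fk.vesicle_overlap(va, va)
        assert res.overlap_fraction == 1.0
        assert np.all(res.per_vesicle["overlap_fraction"] == 1.0)

    def test_disjoint_maps_overlap_zero(self):
        la = np.zeros((20, 20), np.int32)
        lb = np.zeros((20, 20), np.int32)
        la[2:5, 2:5] = 1
        lb[10:14, 10:14] = 1
        import pandas as pd

        va = fk.VesicleSet(la, pd.DataFrame({"label": [1]}))
        vb = fk.VesicleSet(lb, pd.DataFrame({"label": [1]}))
        assert fk.vesicle_overlap(va, vb).overlap_fraction == 0.0

    def test_empty_a_channel_rejected(self):
        import pandas as pd

        empty = fk.VesicleSet(np.zeros((10, 10), np.int32), pd.DataFrame())
        with pytest.raises(ValueError, match="undefined"):
            fk.vesicle_overlap(empty, empty)

    def test_half_colocalized_scene_recovers_half(self):
        ovs = [
            fk.vesicle_overlap(*self._detect_pair(0.5, seed)).overlap_fraction
            for seed in range(10)
        ]
        assert np.mean(ovs) == pytest.approx(0.5, abs=0.05)


class TestFacs:
    def test_equal_means_give_zero(self):
        x = np.array([100.0, 200.0, 300.0])
        assert fk.facs_surface_level(x, x).level == 0.0

    def test_simple_arithmetic(self):
        res = fk.facs_surface_level(np.full(10, 500.0), np.full(8, 200.0))
        assert res.level == 300.0
        assert (res.n_sample, res.n_background) == (10, 8)

    def test_negative_difference_floored(self):
        assert fk.facs_surface_level(np.full(5, 10.0), np.full(5, 90.0)).level == 0.0

    def test_lognormal_shift_recovery(self):
        # additive surface signal on an autofluorescent background population
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            bg = rng.lognormal(5.0, 0.4, 10_000)
            shift = 300.0
            sample = rng.lognormal(5.0, 0.4, 10_000) + shift
            est = fk.facs_surface_level(sample, bg).level
            errs.append(abs(est - shift) / shift)
        assert np.median(errs) < 0.03

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            fk.facs_surface_level(np.array([]), np.array([1.0]))
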