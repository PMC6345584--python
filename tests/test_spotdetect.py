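"""Wavelet transform and vesicle detection: oracles, invariants, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import fluorokit as fk
from fluorokit.spotdetect import atrous_decompose

B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _mirror_index(i: int, n: int) -> int:
    """Whole-sample symmetric reflection: -1 -> 1, n -> n-2."""
    period = 2 * (n - 1)
    i = i % period
    return i if i < n else period - i


def atrous_oracle(img: np.ndarray, n_scales: int):
    """Explicit-loop à trous decomposition used as an independent oracle."""
    smooth = img.astype(float).copy()
    details = []
    for j in range(1, n_scales + 1):
        spacing = 2 ** (j - 1)
        nxt = np.zeros_like(smooth)
        # rows pass
        tmp = np.zeros_like(smooth)
        for r in range(smooth.shape[0]):
            for c in range(smooth.shape[1]):
                acc = 0.0
                for k, w in zip((-2, -1, 0, 1, 2), B3):
                    acc += w * smooth[_mirror_index(r + k * spacing, smooth.shape[0]), c]
                tmp[r, c] = acc
        for r in range(smooth.shape[0]):
            for c in range(smooth.shape[1]):
                acc = 0.0
                for k, w in zip((-2, -1, 0, 1, 2), B3):
                    acc += w * tmp[r, _mirror_index(c + k * spacing, smooth.shape[1])]
                nxt[r, c] = acc
        details.append(smooth - nxt)
        smooth = nxt
    return details, smooth


class TestAtrous:
    @settings(max_examples=20, deadline=None)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(17, 40), st.integers(17, 40)),
            elements=st.floats(0, 1000, allow_nan=False, width=32),
        )
    )
    def test_reconstruction_identity(self, img):
        planes = atrous_decompose(img, 3)
        scale = max(np.abs(img).max(), 1.0)
        assert np.abs(planes.reconstruct() - img).max() / scale < 1e-9

    def test_constant_image_has_zero_detail(self):
        planes = atrous_decompose(np.full((40, 40), 7.0), 3)
        for d in planes.detail:
            assert np.abs(d).max() < 1e-12

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (20, 23))
        details, residual = atrous_oracle(img, 3)
        planes = atrous_decompose(img, 3)
        for d_fast, d_slow in zip(planes.detail, details):
            np.testing.assert_allclose(d_fast, d_slow, atol=1e-10)
        np.testing.assert_allclose(planes.residual, residual, atol=1e-10)

    def test_spot_peak_in_second_detail_plane(self):
        # single Gaussian spot: plane-2 argmax sits on the spot center
        rr, cc = np.indices((33, 33))
        img = 100.0 * np.exp(-((rr - 16) ** 2 + (cc - 16) ** 2) / (2 * 1.5**2))
        details, _ = atrous_oracle(img, 2)
        assert np.unravel_index(np.argmax(details[1]), (33, 33)) == (16, 16)
        planes = atrous_decompose(img, 2)
        assert np.unravel_index(np.argmax(planes.detail[1]), (33, 33)) == (16, 16)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            atrous_decompose(np.zeros((6, 6)), 3)


def _match(detected, true_centers, tol=2.0):
    from scipy.spatial import cKDTree

    if len(detected) == 0:
        return np.zeros(len(true_centers), bool), np.array([])
    d, _ = cKDTree(detected).query(true_centers)
    return d <= tol, d


class TestDetection:
    def test_all_zero_image_gives_empty_set(self):
        vs = fk.detect_vesicles(fk.PixelImage(np.zeros((64, 64))))
        assert vs.n_vesicles == 0
        assert vs.label_map.max() == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_scene_recovery_snr10(self, seed):
        truth = fk.random_scene_truth(25, (256, 256), seed=seed, coloc_fraction=0.0)
        img, _, truth = fk.make_vesicle_scene(truth, (256, 256))
        vs = fk.detect_vesicles(img)
        det = vs.records[["centroid_row", "centroid_col"]].to_numpy()
        matched, dist = _match(det, np.array(truth.vesicle_centers))
        assert matched.all()
        assert dist.max() <= 1.0
        assert vs.n_vesicles <= 26  # at most one spurious split

    def test_count_exact_in_most_runs(self):
        exact = 0
        for seed in range(20):
            truth = fk.random_scene_truth(25, (256, 256), seed=seed)
            img, _, _ = fk.make_vesicle_scene(truth, (256, 256))
            exact += fk.detect_vesicles(img).n_vesicles == 25
        assert exact >= 19  # >= 95% of runs

    def test_watershed_splits_touching_spots(self):
        rr, cc = np.indices((33, 33))
        img = np.full((33, 33), 10.0)
        for center in [(16, 14), (16, 18)]:
            img += 300.0 * np.exp(
                -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * 1.5**2)
            )
        pi = fk.PixelImage(img)
        assert fk.detect_vesicles(pi, fk.DetectionParams(split_touching=True)).n_vesicles == 2
        assert fk.detect_vesicles(pi, fk.DetectionParams(split_touching=False)).n_vesicles == 1

    def test_min_area_monotonicity(self):
        truth = fk.random_scene_truth(25, (256, 256), seed=1)
        img, _, _ = fk.make_vesicle_scene(truth, (256, 256))
        counts = [
            fk.detect_vesicles(img, fk.DetectionParams(min_area=m)).n_vesicles
            for m in (1, 2, 4, 8, 12, 20)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_equivariance(self):
        # spots placed so that neither original nor shifted copies touch borders
        rr, cc = np.indices((128, 128))
        img_arr = np.full((128, 128), 50.0)
        centers = [(30.0, 25.0), (40.0, 80.0), (75.0, 40.0), (90.0, 95.0)]
        for r0, c0 in centers:
            img_arr += 200.0 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * 1.5**2))
        rng = np.random.default_rng(5)
        img_arr += rng.normal(0, 2.0, (128, 128))
        img = fk.PixelImage(img_arr)
        shifted = fk.PixelImage(np.roll(img.values, (7, 11), axis=(0, 1)))
        c0 = fk.detect_vesicles(img).records[["centroid_row", "centroid_col"]].to_numpy()
        c1 = fk.detect_vesicles(shifted).records[["centroid_row", "centroid_col"]].to_numpy()
        c0 = c0[np.lexsort(c0.T)] + [7, 11]
        c1 = c1[np.lexsort(c1.T)]
        assert len(c0) == len(c1)
        np.testing.assert_allclose(c0, c1, atol=0.3)

    def test_intensity_scale_invariance_of_label_map(self):
        truth = fk.random_scene_truth(10, (128, 128), seed=6)
        img, _, _ = fk.make_vesicle_scene(truth, (128, 128))
        vs1 = fk.detect_vesicles(img)
        vs2 = fk.detect_vesicles(fk.PixelImage(img.values * 37.5))
        np.testing.assert_array_equal(vs1.label_map, vs2.label_map)

    def test_statistics_measured_on_original_image(self):
        truth = fk.random_scene_truth(5, (96, 96), seed=2, noise_sigma=0.0)
        img, _, _ = fk.make_vesicle_scene(truth, (96, 96))
        vs = fk.detect_vesicles(img)
        for _, row in vs.records.iterrows():
            pix = img.values[vs.label_map == row["label"]]
            assert row["mean_intensity"] == pytest.approx(pix.mean())
            assert row["total_intensity"] == pytest.approx(pix.sum())

    def test_area_um2_uses_pixel_size(self):
        truth = fk.random_scene_truth(3, (96, 96), seed=2)
        img, _, _ = fk.make_vesicle_scene(truth, (96, 96))
        img = fk.PixelImage(img.values, pixel_size=0.1)
        vs = fk.detect_vesicles(img)
        np.testing.assert_allclose(
            vs.records["area_um2"], vs.records["area_px"] * 0.01
        )


class TestTimecourse:
    def test_counts_follow_spot_numbers(self):
        frames = []
        for i, n in enumerate((5, 10, 15)):
            truth = fk.random_scene_truth(n, (192, 192), seed=40 + i)
            img, _, _ = fk.make_vesicle_scene(truth, (192, 192))
            frames.append(fk.PixelImage(img.values, frame_index=i))
        table = fk.vesicle_timecourse(frames)
        assert list(table["frame_index"]) == [0, 1, 2]
        assert list(table["vesicle_count"]) == [5, 10, 15]

    def test_identical_frames_identical_rows(self):
        truth = fk.random_scene_truth(8, (128, 128), seed=3)
        img, _, _ = fk.make_vesicle_scene(truth, (128, 128))
        frames = [fk.PixelImage(img.values, frame_index=i) for i in range(3)]
        table = fk.vesicle_timecourse(frames)
        assert table.drop(columns="frame_index").nunique().max() == 1

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fk.vesicle_timecourse([])

    def test_shape_mismatch_rejected(self):
        frames = [fk.PixelImage(np.zeros((32, 32))), fk.PixelImage(np.zeros((33, 32)))]
        with pytest.raises(ValueError, match="mismatch"):
            fk.vesicle_timecourse(frames)
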