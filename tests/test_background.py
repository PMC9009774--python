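import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fretstack.background import (
    BackgroundFailure,
    cluster_tiles,
    compute_tile_features,
    estimate_background_surface,
    frame_features,
    normalize_features,
    process_frame_background,
    process_stack_background,
    subtract_background,
    tile_image,
)
from fretstack.core_io import ImageStack, RunConfig, FrameRange

from oracles import dbscan_equivalent, dbscan_oracle


class TestTiling:
    def test_printed_640x480_window40_arithmetic(self):
        grid = tile_image(np.zeros((480, 640), dtype=np.uint16), 40)
        assert grid.tile_size == 16
        assert grid.n_cols == 40 and grid.n_rows == 30
        assert grid.n_tiles == 1200

    def test_single_tile_identity(self):
        grid = tile_image(np.zeros((16, 16)), 1)
        assert grid.n_tiles == 1 and grid.tile_size == 16

    def test_remainder_strips_are_untiled(self):
        grid = tile_image(np.zeros((481, 645)), 40)
        assert grid.tile_size == 16
        assert grid.n_cols == 40 and grid.n_rows == 30
        # 645 - 40*16 = 5 px right strip, 481 - 30*16 = 1 px bottom strip
        assert grid.n_cols * grid.tile_size == 640
        assert grid.n_rows * grid.tile_size == 480

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((32, 32)), 30)

    def test_tiles_are_views_of_expected_blocks(self):
        frame = np.arange(64).reshape(8, 8)
        grid = tile_image(frame, 2)
        np.testing.assert_array_equal(grid.tile(1, 0), frame[4:8, 0:4])


class TestTileFeatures:
    def test_constant_tile_conventions(self):
        f = compute_tile_features(np.full((6, 6), 7))
        med, std, skew, kurt, cx, cy = f
        assert (med, std, skew, kurt) == (7, 0, 0, 0)
        assert (cx, cy) == (2.5, 2.5)

    def test_two_by_two_moments_by_hand(self):
        # [[0,0],[0,4]]: mean 1, var 3; all weight at the (1,1) corner
        f = compute_tile_features(np.array([[0, 0], [0, 4]]))
        assert f[0] == 0.0
        assert f[1] == pytest.approx(np.sqrt(3.0))
        assert (f[4], f[5]) == (1.0, 1.0)
        # standardized moments of {0,0,0,4}
        vals = np.array([0, 0, 0, 4.0])
        z = (vals - 1.0) / np.sqrt(3.0)
        assert f[2] == pytest.approx((z**3).mean())
        assert f[3] == pytest.approx((z**4).mean() - 3.0)

    def test_all_zero_tile_centroid_falls_back_to_center(self):
        f = compute_tile_features(np.zeros((4, 4)))
        assert (f[4], f[5]) == (1.5, 1.5)

    @given(
        tile=hnp.arrays(
            np.int64, (5, 5), elements=st.integers(min_value=0, max_value=4095)
        )
    )
    def test_rotation_by_180_degrees_fixes_moments_and_reflects_centroid(self, tile):
        f = compute_tile_features(tile)
        g = compute_tile_features(tile[::-1, ::-1])
        np.testing.assert_allclose(f[:4], g[:4], atol=1e-9)
        assert g[4] == pytest.approx(4 - f[4])
        assert g[5] == pytest.approx(4 - f[5])


class TestNormalizeFeatures:
    def test_output_has_zero_median_unit_iqr(self, rng):
        F = rng.normal(50, 10, size=(40, 6)) * np.array([100, 5, 1, 1, 3, 3])
        N = normalize_features(F)
        np.testing.assert_allclose(np.median(N, axis=0), 0, atol=1e-12)
        q75, q25 = np.percentile(N, [75, 25], axis=0)
        np.testing.assert_allclose(q75 - q25, 1, atol=1e-12)

    def test_idempotent_on_standardized_input(self, rng):
        F = rng.normal(size=(30, 6))
        N = normalize_features(F)
        np.testing.assert_allclose(normalize_features(N), N, atol=1e-12)

    def test_identical_tiles_map_to_zeros(self):
        F = np.tile([3.0, 1.0, 0.2, -0.1, 7.5, 7.5], (10, 1))
        np.testing.assert_array_equal(normalize_features(F), np.zeros((10, 6)))


class TestClustering:
    def test_two_separated_groups_dimmer_is_background(self, rng):
        lo = rng.normal(0, 0.05, size=(12, 6))
        hi = rng.normal(10, 0.05, size=(9, 6))
        X = np.vstack([lo, hi])
        medians = np.r_[np.full(12, 20.0), np.full(9, 500.0)]
        labels = cluster_tiles(X, eps=1.0, min_samples=5, raw_medians=medians)
        assert labels.n_clusters == 2
        assert labels.background_mask[:12].all()
        assert not labels.background_mask[12:].any()

    def test_identical_points_one_background_cluster(self):
        X = np.zeros((8, 6))
        labels = cluster_tiles(X, eps=0.5, min_samples=5, raw_medians=np.full(8, 3.0))
        assert labels.n_clusters == 1
        assert labels.background_mask.all()

    def test_min_samples_above_count_signals_failure(self):
        X = np.zeros((4, 6))
        with pytest.raises(BackgroundFailure):
            cluster_tiles(X, eps=0.5, min_samples=10)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(5, 31))
            dim = int(rng.integers(2, 7))
            X = rng.normal(0, 1, size=(n, dim)) * rng.choice([0.3, 1.0, 3.0])
            eps = float(rng.uniform(0.2, 2.0))
            min_samples = int(rng.integers(2, 7))
            expected = dbscan_oracle(X, eps, min_samples)
            if (expected != -1).sum() == 0:
                with pytest.raises(BackgroundFailure):
                    cluster_tiles(X, eps, min_samples)
                continue
            got = cluster_tiles(X, eps, min_samples)
            assert dbscan_equivalent(got.labels, expected, X, eps, min_samples), (
                f"trial {trial}: labels disagree with density-reachability oracle"
            )

    def test_clustered_point_set_grows_with_eps(self, rng):
        # monotonicity that DBSCAN actually has: enlarging eps never turns a
        # clustered point into noise (cluster *count* is not monotone)
        X = rng.normal(0, 1, size=(60, 4))
        prev = np.zeros(60, dtype=bool)
        for eps in [0.3, 0.6, 1.0, 1.5, 2.5]:
            try:
                labels = cluster_tiles(X, eps, 4)
                clustered = labels.labels != -1
            except BackgroundFailure:
                clustered = np.zeros(60, dtype=bool)
            assert (prev <= clustered).all()
            prev = clustered


class TestBackgroundSurface:
    def quadratic_grid(self, coeffs=(100.0, 0.05, 0.02, 1e-4, 0.0, 0.0)):
        frame = np.zeros((480, 640))
        grid = tile_image(frame, 40)
        xs, ys = grid.tile_centers()
        a0, a1, a2, a3, a4, a5 = coeffs
        z = a0 + a1 * xs + a2 * ys + a3 * xs**2 + a4 * xs * ys + a5 * ys**2
        return grid, z

    def test_exact_quadratic_reproduced_everywhere(self):
        grid, z = self.quadratic_grid()
        surface = estimate_background_surface(grid, np.ones(grid.n_tiles, bool), z)
        X, Y = np.meshgrid(np.arange(640.0), np.arange(480.0))
        truth = 100 + 0.05 * X + 0.02 * Y + 1e-4 * X**2
        assert np.abs(surface - truth).max() < 0.5

    def test_constant_background_reproduced(self):
        grid, _ = self.quadratic_grid()
        surface = estimate_background_surface(
            grid, np.ones(grid.n_tiles, bool), np.full(grid.n_tiles, 50.0)
        )
        np.testing.assert_allclose(surface, 50.0, atol=1e-6)

    def test_surface_under_excluded_object_matches_surroundings(self):
        grid, z = self.quadratic_grid()
        bg = np.ones(grid.n_tiles, bool)
        # carve a foreground blob out of the node set
        idx = np.arange(grid.n_tiles).reshape(grid.n_rows, grid.n_cols)
        bg[idx[10:20, 15:25].ravel()] = False
        z_noisy = z + np.random.default_rng(3).normal(0, 0.3, z.shape)
        surface = estimate_background_surface(grid, bg, z_noisy)
        X, Y = np.meshgrid(np.arange(640.0), np.arange(480.0))
        truth = 100 + 0.05 * X + 0.02 * Y + 1e-4 * X**2
        hole = (slice(160, 320), slice(240, 400))
        assert np.abs(surface[hole] - truth[hole]).max() < 2.0

    def test_too_few_background_tiles_fails(self):
        grid, z = self.quadratic_grid()
        bg = np.zeros(grid.n_tiles, bool)
        bg[:5] = True
        with pytest.raises(BackgroundFailure):
            estimate_background_surface(grid, bg, z)

    def test_six_tiles_suffice_via_polynomial_fallback(self):
        grid, z = self.quadratic_grid(coeffs=(80.0, 0.03, 0.01, 0.0, 0.0, 0.0))
        bg = np.zeros(grid.n_tiles, bool)
        idx = np.arange(grid.n_tiles).reshape(grid.n_rows, grid.n_cols)
        for r, c in [(0, 0), (0, 20), (0, 39), (29, 0), (15, 20), (29, 39)]:
            bg[idx[r, c]] = True
        surface = estimate_background_surface(grid, bg, z)
        assert np.isfinite(surface).all()
        X, Y = np.meshgrid(np.arange(640.0), np.arange(480.0))
        truth = 80 + 0.03 * X + 0.01 * Y
        assert np.abs(surface - truth).max() < 0.5


class TestSubtraction:
    def test_exact_cancellation(self):
        frame = np.full((8, 8), 120, dtype=np.uint16)
        out = subtract_background(frame, np.full((8, 8), 120.0), 16)
        assert out.dtype == np.uint16
        assert not out.any()

    def test_object_peak_survives_subtraction(self, rng):
        surface = 100 + 0.1 * np.arange(64)[None, :] + np.zeros((64, 64))
        obj = np.zeros((64, 64))
        obj[30, 30] = 200
        frame = np.rint(surface + obj).astype(np.uint16)
        out = subtract_background(frame, surface, 16)
        assert abs(int(out[30, 30]) - 200) <= 1

    def test_never_negative_when_surface_exceeds_frame(self):
        frame = np.full((4, 4), 10, dtype=np.uint16)
        out = subtract_background(frame, np.full((4, 4), 50.0), 16)
        assert (out == 0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((4, 4), dtype=np.uint16), np.zeros((5, 4)), 16)


class TestStackProcessing:
    def test_worker_count_does_not_change_output(self, small_fixture):
        donor, _, _ = small_fixture
        donor = ImageStack(donor.frames[:4], donor.bit_depth, donor.frame_ids[:4], "donor")
        cfg = RunConfig(window=20)
        out1, res1 = process_stack_background(donor, cfg, n_jobs=1)
        out4, res4 = process_stack_background(donor, cfg, n_jobs=4)
        np.testing.assert_array_equal(out1.frames, out4.frames)
        assert [r.flags for r in res1] == [r.flags for r in res4]

    def test_per_range_eps_recorded(self, small_fixture):
        donor, _, _ = small_fixture
        cfg = RunConfig(
            window=20,
            frame_ranges=[FrameRange(0, 2, 1.2), FrameRange(3, 5, 2.5)],
        )
        _, results = process_stack_background(donor, cfg, n_jobs=1)
        assert [r.eps for r in results] == [1.2, 1.2, 1.2, 2.5, 2.5, 2.5]

    def test_residual_background_below_half_noise_sigma(self, small_fixture):
        donor, _, truth = small_fixture
        cfg = RunConfig(window=20)
        corrected, results = process_stack_background(donor, cfg, n_jobs=1)
        assert not any(r.failed for r in results)
        sigma = truth.noise_sigma
        for t in range(corrected.n_frames):
            resid = corrected.frames[t].astype(float)[truth.background_region[t]]
            assert resid.mean() <= sigma / 2
            assert resid.std() <= sigma

    def test_failed_frame_passes_through_with_flag(self):
        # pure-noise frame with min_samples too high for any cluster
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 4096, size=(64, 64)).astype(np.uint16)
        result = process_frame_background(frame, 0, 16, 8, eps=1e-6, min_samples=60)
        assert result.failed
        np.testing.assert_array_equal(result.corrected, frame)
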