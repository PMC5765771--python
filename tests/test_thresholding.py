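"""Tests for seed statistics, the cluster threshold, and Lee-based denoising."""

import numpy as np
import pytest

from mwdhseg import (
    DegenerateInputError,
    LeeParams,
    SeedPoint,
    SeedStats,
    ValidationError,
    apply_high_threshold,
    apply_low_threshold,
    collect_seed_stats,
    compute_low_threshold,
    estimate_noise_sigma,
    lee_filter,
)


class TestSeedStats:
    def test_constant_window(self):
        img = np.full((9, 9), 7.0)
        s = collect_seed_stats(img, SeedPoint(4, 4), 1)
        assert (s.mean, s.variance, s.sample_size) == (7.0, 0.0, 9)

    def test_hand_computed_window(self):
        img = np.arange(1.0, 10.0).reshape(3, 3)
        s = collect_seed_stats(img, SeedPoint(1, 1), 1)
        assert s.mean == pytest.approx(5.0)
        assert s.variance == pytest.approx(20.0 / 3.0)  # population variance

    def test_corner_window_is_clipped(self):
        img = np.ones((5, 5))
        s = collect_seed_stats(img, SeedPoint(0, 0), 1)
        assert s.sample_size == 4

    def test_out_of_bounds_seed(self):
        with pytest.raises(IndexError):
            collect_seed_stats(np.ones((5, 5)), SeedPoint(5, 0), 1)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValidationError):
            SeedStats(mean=0.0, variance=-1.0, sample_size=4)


class TestClusterThreshold:
    def test_two_delta_population_fixed_point(self):
        """90% of pixels at 4, 10% at 12, seed in the 12s: classes converge to
        means 4 and 12, so the threshold is exactly their midpoint, 8."""
        values = np.array([4.0] * 90 + [12.0] * 10).reshape(10, 10)
        stats = SeedStats(mean=12.0, variance=0.0, sample_size=9)
        assert compute_low_threshold(values, stats) == pytest.approx(8.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_two_gaussians_threshold_between_modes(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(30.0, 2.0, 800)
        b = rng.normal(60.0, 2.0, 800)
        band = np.concatenate([a, b]).reshape(40, 40)
        stats = SeedStats(mean=60.0, variance=4.0, sample_size=9)
        t = compute_low_threshold(band, stats)
        assert 40.0 < t < 50.0

    def test_constant_band_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_low_threshold(np.full((4, 4), 3.0), SeedStats(3.0, 0.0, 9))

    def test_affine_equivariance(self, rng):
        band = rng.normal(50.0, 10.0, (20, 20))
        stats = SeedStats(mean=65.0, variance=4.0, sample_size=9)
        t = compute_low_threshold(band, stats)
        a, b = 2.5, -7.0
        stats2 = SeedStats(mean=a * 65.0 + b, variance=a * a * 4.0, sample_size=9)
        t2 = compute_low_threshold(a * band + b, stats2)
        assert t2 == pytest.approx(a * t + b, rel=1e-6)

    def test_pixel_order_invariance(self, rng):
        band = rng.normal(0.0, 1.0, (12, 12))
        stats = SeedStats(mean=1.0, variance=1.0, sample_size=9)
        t1 = compute_low_threshold(band, stats)
        shuffled = rng.permutation(band.ravel()).reshape(band.shape)
        t2 = compute_low_threshold(shuffled, stats)
        assert t1 == pytest.approx(t2, abs=1e-9)


class TestApplyLowThreshold:
    def test_seed_on_bright_side(self):
        band = np.array([[1.0, 9.0], [1.0, 9.0]])
        mask = apply_low_threshold(band, 5.0, SeedPoint(0, 1))
        np.testing.assert_array_equal(mask, [[0, 1], [0, 1]])

    def test_seed_on_dark_side_flips_selection(self):
        band = np.array([[1.0, 9.0], [1.0, 9.0]])
        mask = apply_low_threshold(band, 5.0, SeedPoint(0, 0))
        np.testing.assert_array_equal(mask, [[1, 0], [1, 0]])

    def test_seed_exactly_at_threshold_counts_as_above(self):
        band = np.array([[5.0, 1.0], [9.0, 1.0]])
        mask = apply_low_threshold(band, 5.0, SeedPoint(0, 0))
        np.testing.assert_array_equal(mask, [[1, 0], [1, 0]])

    def test_two_class_fraction_recovered(self):
        rng = np.random.default_rng(7)
        frac = 0.3
        n = 10000
        labels = rng.random(n) < frac
        band = np.where(labels, rng.normal(60, 2, n), rng.normal(30, 2, n))
        band = band.reshape(100, 100)
        seed = SeedPoint(*np.argwhere(band > 45)[0])
        mask = apply_low_threshold(band, 45.0, seed)
        assert abs(mask.mean() - labels.mean()) < 0.02


class TestNoiseSigma:
    def test_gaussian_band_recovers_sigma(self):
        rng = np.random.default_rng(11)
        band = rng.normal(0.0, 2.0, (100, 100))
        assert 1.9 <= estimate_noise_sigma(band) <= 2.1

    def test_zero_band(self):
        assert estimate_noise_sigma(np.zeros((10, 10))) == 0.0

    def test_robust_to_outliers(self):
        rng = np.random.default_rng(5)
        band = rng.normal(0.0, 1.0, 10000)
        idx = rng.choice(10000, 100, replace=False)
        band[idx] = np.where(rng.random(100) < 0.5, 50.0, -50.0)
        sigma = estimate_noise_sigma(band.reshape(100, 100))
        assert 0.95 <= sigma <= 1.1

    def test_uses_finest_diagonal_band(self, bank, rng):
        from mwdhseg import analyze_2d

        img = rng.normal(0.0, 3.0, (64, 64))
        bands = analyze_2d(img, bank)
        assert estimate_noise_sigma(bands) == estimate_noise_sigma(bands[(1, 1)])


class TestLeeFilter:
    def test_zero_noise_is_exact_identity(self, rng):
        band = rng.normal(size=(8, 8))
        out = lee_filter(band, LeeParams(noise_sigma=0.0))
        np.testing.assert_array_equal(out, band)

    def test_locally_constant_region_returns_local_mean(self):
        band = np.full((7, 7), 4.0)
        out = lee_filter(band, LeeParams(noise_sigma=2.0))
        np.testing.assert_allclose(out, 4.0)

    def test_hand_evaluated_center_pixel(self):
        """Window {0,0,0,10,10,10,0,0,0} at center 10 with sigma_n^2 = 1:
        m = 10/3, v = 200/9, k = 191/200, output 291/30 = 9.7 exactly."""
        band = np.zeros((3, 3))
        band[1, :] = 10.0
        out = lee_filter(band, LeeParams(window_radius=1, noise_sigma=1.0))
        assert out[1, 1] == pytest.approx(291.0 / 30.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        """On small bands the vectorized filter equals a per-pixel hand
        evaluation of m + k (w - m) over the clipped window, bitwise
        (window elements summed one by one in reading order)."""
        params = LeeParams(window_radius=1, noise_sigma=0.7)
        for shape in [(3, 3), (4, 6), (6, 6)]:
            band = rng.normal(size=shape)
            out = lee_filter(band, params)
            expected = np.empty(shape)
            for i in range(shape[0]):
                for j in range(shape[1]):
                    win = band[max(0, i - 1) : i + 2, max(0, j - 1) : j + 2]
                    s = sq = 0.0
                    for value in win.ravel():
                        s += value
                        sq += value * value
                    n = win.size
                    m = s / n
                    v = max(sq / n - m * m, 0.0)
                    k = max(v - params.noise_sigma**2, 0.0) / v if v > 0 else 0.0
                    expected[i, j] = m + k * (band[i, j] - m)
            np.testing.assert_array_equal(out, expected)

    def test_nonfinite_rejected(self):
        band = np.ones((4, 4))
        band[0, 0] = np.inf
        with pytest.raises(ValidationError):
            lee_filter(band, LeeParams(noise_sigma=1.0))


class TestHardThreshold:
    def test_zero_threshold_keeps_band(self, rng):
        band = rng.normal(size=(5, 5))
        np.testing.assert_array_equal(apply_high_threshold(band, 0.0), band)

    def test_direct_rule(self):
        band = np.array([[-5.0, -2.0, 0.0, 2.0, 5.0]])
        out = apply_high_threshold(band, 3.0)
        np.testing.assert_array_equal(out, [[-5.0, 0.0, 0.0, 0.0, 5.0]])

    def test_all_small_coefficients_zeroed(self, rng):
        band = rng.uniform(-1.0, 1.0, (6, 6))
        np.testing.assert_array_equal(apply_high_threshold(band, 2.0), 0.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            apply_high_threshold(np.ones((3, 3)), -1.0)

    def test_zeroed_set_monotone_in_threshold(self, rng):
        band = rng.normal(0, 3, (16, 16))
        zeroed_sets = [apply_high_threshold(band, t) == 0 for t in [0.5, 1.5, 3.0, 6.0]]
        for small, large in zip(zeroed_sets, zeroed_sets[1:]):
            assert np.all(large[small])  # small-threshold zero set ⊆ larger one
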