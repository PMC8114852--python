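from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.stats import ortho_group

from _oracles import exhaustive_disparity_p

from tarsomorph import (
    bhattacharyya,
    bootstrap_disparity,
    disparity_metric,
    permutation_disparity_test,
    rarefied_disparity,
    wilcoxon_ranksum,
)


class TestMetrics:
    def test_single_point_has_zero_spread(self):
        X = np.array([[1.0, 2.0, 3.0]])
        assert disparity_metric(X, "sum_of_ranges") == 0.0
        assert disparity_metric(X, "sum_of_variances") == 0.0

    def test_hand_examples(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert disparity_metric(X, "sum_of_ranges") == pytest.approx(3.0)
        assert disparity_metric(X, "sum_of_variances") == pytest.approx(2.5)
        tri = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        assert disparity_metric(tri, "mean_pairwise_distance") == pytest.approx(4.0)

    def test_rotation_invariance_of_variance_and_mpd_but_not_ranges(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 3))
        Q = ortho_group.rvs(3, random_state=1)
        XQ = X @ Q
        for metric in ("sum_of_variances", "mean_pairwise_distance"):
            assert disparity_metric(XQ, metric) == pytest.approx(
                disparity_metric(X, metric), rel=1e-10
            )
        # sum of ranges is axis-dependent: a generic rotation changes it
        assert disparity_metric(XQ, "sum_of_ranges") != pytest.approx(
            disparity_metric(X, "sum_of_ranges"), rel=1e-6
        )

    def test_sum_of_variances_equals_pairwise_distance_identity(self):
        # sum over axes of var (n-1 denom) = sum of squared pairwise
        # distances / (n (n-1))
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(3, 20), rng.integers(1, 6)))
            n = X.shape[0]
            d2 = sum(
                np.sum((X[i] - X[j]) ** 2) for i, j in combinations(range(n), 2)
            )
            assert disparity_metric(X, "sum_of_variances") == pytest.approx(
                d2 / (n * (n - 1)), rel=1e-10
            )

    def test_duplicating_taxa_preserves_ranges(self):
        X = np.random.default_rng(3).normal(size=(8, 3))
        doubled = np.vstack([X, X])
        assert disparity_metric(doubled, "sum_of_ranges") == pytest.approx(
            disparity_metric(X, "sum_of_ranges")
        )

    def test_mpd_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            disparity_metric(np.array([[1.0, 2.0]]), "mean_pairwise_distance")


class TestBootstrap:
    def test_identical_rows_give_zero_everywhere(self):
        X = np.tile([1.0, 2.0], (10, 1))
        res = bootstrap_disparity(X, "sum_of_ranges", n_boot=50, seed=0)
        assert np.all(res.bootstrap_values == 0.0)

    def test_pseudoreplicate_count_contract(self):
        X = np.random.default_rng(1).normal(size=(12, 3))
        res = bootstrap_disparity(X, "sum_of_variances", n_boot=200, seed=0)
        assert len(res.bootstrap_values) == 200
        assert res.ci_low <= np.median(res.bootstrap_values) <= res.ci_high

    def test_bootstrap_mean_tracks_analytic_variance(self):
        # large Gaussian group: E[sum of variances] = sum of true variances,
        # and the bootstrap mean carries only the small (1 - 1/n) bias
        sigma2 = np.array([1.0, 4.0, 0.25])
        X = np.random.default_rng(2).normal(0, np.sqrt(sigma2), size=(500, 3))
        res = bootstrap_disparity(X, "sum_of_variances", n_boot=200, seed=3)
        assert res.bootstrap_values.mean() == pytest.approx(sigma2.sum(), rel=0.05)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(4).normal(size=(10, 2))
        a = bootstrap_disparity(X, "mean_pairwise_distance", 100, seed=9)
        b = bootstrap_disparity(X, "mean_pairwise_distance", 100, seed=9)
        np.testing.assert_array_equal(a.bootstrap_values, b.bootstrap_values)


class TestRarefaction:
    def test_degenerate_range_equals_bootstrap(self):
        X = np.random.default_rng(5).normal(size=(15, 3))
        rr = rarefied_disparity(X, "sum_of_variances", (15, 15), n_boot=100, seed=7)
        br = bootstrap_disparity(X, "sum_of_variances", n_boot=100, seed=7)
        np.testing.assert_array_equal(rr.bootstrap_values, br.bootstrap_values)
        assert rr.rarefied_mean == pytest.approx(br.bootstrap_values.mean())

    def test_expected_ranges_non_decreasing_in_level(self):
        # order statistics: the expected range grows with subsample size;
        # average the rarefaction curve over 20 datasets to beat MC noise
        rng = np.random.default_rng(6)
        curves = []
        for seed in range(20):
            X = rng.normal(size=(12, 2))
            rr = rarefied_disparity(X, "sum_of_ranges", (2, 12), n_boot=150, seed=seed)
            curves.append(
                [rr.rarefaction_levels[s].mean() for s in sorted(rr.rarefaction_levels)]
            )
        means = np.mean(curves, axis=0)
        assert all(m2 >= m1 - 0.02 for m1, m2 in zip(means, means[1:]))

    def test_matches_from_scratch_reference(self):
        """5-point toy group vs an independently coded rarefaction loop."""
        X = np.arange(10, dtype=float).reshape(5, 2)
        seed, n_boot = 13, 40
        rr = rarefied_disparity(X, "sum_of_ranges", (2, 5), n_boot=n_boot, seed=seed)
        rng = np.random.default_rng(seed)
        expected_levels = {}
        for size in range(2, 6):
            vals = []
            for _ in range(n_boot):
                idx = rng.integers(0, 5, size=size)
                sub = X[idx]
                vals.append(np.sum(sub.max(axis=0) - sub.min(axis=0)))
            expected_levels[size] = np.array(vals)
        for size in range(2, 6):
            np.testing.assert_allclose(rr.rarefaction_levels[size], expected_levels[size])
        assert rr.rarefied_mean == pytest.approx(
            np.mean([expected_levels[s].mean() for s in range(2, 6)])
        )

    def test_invalid_range_rejected(self):
        X = np.random.default_rng(7).normal(size=(6, 2))
        with pytest.raises(ValueError):
            rarefied_disparity(X, "sum_of_ranges", (2, 10))

    def test_without_replacement_mode_at_full_size_is_exact(self):
        X = np.random.default_rng(8).normal(size=(6, 2))
        rr = rarefied_disparity(
            X, "sum_of_ranges", (6, 6), n_boot=10, seed=0, with_replacement=False
        )
        assert np.all(rr.bootstrap_values == disparity_metric(X, "sum_of_ranges"))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample(self):
        _, p = wilcoxon_ranksum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_exact_and_asymptotic_paths_agree(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 15)
        _, p_exact = wilcoxon_ranksum(a, b)  # 225 <= 400, tie-free -> exact
        from scipy.stats import mannwhitneyu

        p_approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p_exact == pytest.approx(p_approx, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestBhattacharyya:
    def test_self_overlap_is_one(self):
        x = np.random.default_rng(10).normal(size=30)
        assert bhattacharyya(x, x) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert bhattacharyya([0.0, 0.1, 0.2], [10.0, 10.1, 10.2], n_bins=2) == 0.0

    def test_hand_binned_example(self):
        # 2 bins on [0, 4]: a -> (3/4, 1/4), b -> (1/4, 3/4)
        a = [0.0, 1.0, 1.5, 3.0]
        b = [1.0, 3.0, 3.5, 4.0]
        expected = np.sqrt(0.75 * 0.25) + np.sqrt(0.25 * 0.75)
        assert bhattacharyya(a, b, n_bins=2) == pytest.approx(expected)

    def test_default_bin_rule(self):
        a = np.random.default_rng(11).normal(size=8)
        b = np.random.default_rng(12).normal(size=8)
        # floor(sqrt(16)) = 4 bins: same as explicit n_bins=4
        assert bhattacharyya(a, b) == pytest.approx(bhattacharyya(a, b, n_bins=4))


class TestPermutationTest:
    @pytest.mark.parametrize("metric", ["sum_of_ranges", "sum_of_variances"])
    def test_exhaustive_mode_equals_enumeration(self, metric):
        rng = np.random.default_rng(13)
        A = rng.normal(0, 1, (3, 2))
        B = rng.normal(0, 3, (3, 2))
        res = permutation_disparity_test(A, B, metric, exhaustive=True)
        assert res["n_perm"] == comb(6, 3)
        assert res["p"] == pytest.approx(exhaustive_disparity_p(A, B, metric))

    def test_minimal_attainable_p_for_extreme_variance_ratio(self):
        rng = np.random.default_rng(14)
        A = rng.normal(0, 100, (10, 2))
        B = rng.normal(0, 0.01, (10, 2))
        res = permutation_disparity_test(A, B, "sum_of_variances", n_perm=199, seed=1)
        assert res["p"] == pytest.approx(1 / 200)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        A = rng.normal(size=(5, 2))
        B = rng.normal(size=(6, 2))
        r1 = permutation_disparity_test(A, B, "sum_of_ranges", n_perm=99, seed=3)
        r2 = permutation_disparity_test(A, B, "sum_of_ranges", n_perm=99, seed=3)
        assert r1 == r2
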