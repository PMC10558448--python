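import numpy as np
import pytest
from scipy import stats

import imputequal as iq
from imputequal.data import Dataset, FeatureSchema


class TestSampleDirections:
    def test_unit_norms(self):
        dirs = iq.sample_directions(6, 20, seed=0)
        assert np.allclose(np.linalg.norm(dirs.directions, axis=1), 1.0,
                           atol=1e-12)

    def test_one_dimensional_sphere(self):
        dirs = iq.sample_directions(1, 10, seed=1)
        assert np.isin(dirs.directions.ravel(), (-1.0, 1.0)).all()

    def test_default_m_is_twice_d(self):
        assert iq.sample_directions(7, seed=2).m == 14
        assert iq.default_n_directions(7) == 14

    def test_m_below_d_rejected(self):
        with pytest.raises(ValueError, match="M >= d"):
            iq.sample_directions(5, 4, seed=0)

    def test_isotropy(self):
        dirs = iq.sample_directions(5, 10000, seed=3)
        assert np.linalg.norm(dirs.directions.mean(axis=0)) < 0.05

    def test_deterministic(self):
        a = iq.sample_directions(4, 8, seed=4)
        b = iq.sample_directions(4, 8, seed=4)
        assert np.array_equal(a.directions, b.directions)


class TestHalfPartitions:
    def test_odd_n_sizes(self):
        parts = iq.make_half_partitions(7, 5, seed=0)
        for I, J in parts.pairs:
            assert I.size == 4 and J.size == 3

    def test_even_split(self):
        parts = iq.make_half_partitions(10, 3, seed=1)
        for I, J in parts.pairs:
            assert I.size == J.size == 5

    def test_cover_and_disjoint(self):
        parts = iq.make_half_partitions(23, 4, seed=2)
        for I, J in parts.pairs:
            assert np.intersect1d(I, J).size == 0
            assert np.array_equal(np.union1d(I, J), np.arange(23))

    def test_default_p_is_ten(self):
        assert iq.make_half_partitions(20, seed=0).p == 10

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            iq.make_half_partitions(3, 2, seed=0)


def table_for(truth, imputed, m=10, p=5, seed=0):
    dirs = iq.sample_directions(truth.n_features, m, seed=seed)
    parts = iq.make_half_partitions(truth.n_samples, p, seed=seed + 1)
    return iq.sw_distance_table(truth, imputed, dirs, parts)


class TestDistanceTable:
    def test_perfect_imputation_exact_equality(self, small_dataset):
        table = table_for(small_dataset, small_dataset.values)
        assert np.array_equal(table.w, table.w_hat)
        assert table.skipped == []

    def test_scale_invariance(self, small_dataset):
        imputed = small_dataset.values + np.random.default_rng(0).normal(
            0, 0.1, small_dataset.values.shape
        )
        base = table_for(small_dataset, imputed)
        scaled_truth = Dataset(small_dataset.values * 7.3, small_dataset.schema,
                               small_dataset.labels)
        scaled = table_for(scaled_truth, imputed * 7.3)
        assert np.allclose(scaled.w, base.w, rtol=1e-10)
        assert np.allclose(scaled.w_hat, base.w_hat, rtol=1e-10)

    def test_one_dimensional_matches_marginal_w2(self):
        rng = np.random.default_rng(5)
        truth = Dataset(rng.normal(size=(40, 1)),
                        [FeatureSchema("x", "continuous")])
        imputed = truth.values + rng.normal(0, 0.2, (40, 1))
        dirs = iq.sample_directions(1, 3, seed=6)
        parts = iq.make_half_partitions(40, 4, seed=7)
        table = iq.sw_distance_table(truth, imputed, dirs, parts)
        for r in range(3):
            sign = dirs.directions[r, 0]
            for p, (I, J) in enumerate(parts.pairs):
                s = (sign * truth.values[I, 0]).std()
                expect = iq.wasserstein2_1d(
                    sign * truth.values[I, 0] / s, sign * imputed[J, 0] / s
                )
                assert table.w_hat[r, p] == pytest.approx(expect)

    def test_odd_sample_count(self):
        rng = np.random.default_rng(8)
        truth = Dataset(rng.normal(size=(41, 3)),
                        [FeatureSchema(f"x{j}", "continuous") for j in range(3)])
        table = table_for(truth, truth.values, m=4, p=3)
        assert np.array_equal(table.w, table.w_hat)
        assert np.isfinite(table.w).all()

    def test_degenerate_direction_skipped(self):
        # constant data: every projection has zero sd
        values = np.ones((10, 2))
        truth = Dataset(values, [FeatureSchema("a", "continuous"),
                                 FeatureSchema("b", "continuous")])
        with pytest.raises(ValueError, match="degenerate"):
            table_for(truth, values, m=3, p=2)

    def test_leftover_missing_rejected(self, small_dataset):
        bad = small_dataset.values.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            table_for(small_dataset, bad)

    def test_rotation_equivariance_in_distribution(self):
        """A fixed orthogonal map of both matrices leaves the distribution
        of table entries unchanged across direction draws."""
        rng = np.random.default_rng(9)
        d, n = 3, 100
        X = rng.normal(size=(n, d)) @ np.diag([2.0, 1.0, 0.5])
        Xh = X + rng.normal(0, 0.3, X.shape)
        Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        schema = [FeatureSchema(f"x{j}", "continuous") for j in range(d)]
        parts = iq.make_half_partitions(n, 2, seed=10)
        dirs = iq.sample_directions(d, 500, seed=11)
        t1 = iq.sw_distance_table(Dataset(X, schema), Xh, dirs, parts)
        t2 = iq.sw_distance_table(Dataset(X @ Q, schema), Xh @ Q, dirs, parts)
        p = stats.ks_2samp(t1.flattened()[1], t2.flattened()[1]).pvalue
        assert p > 0.001


class TestClassCReport:
    def test_perfect_imputation(self, small_dataset):
        table = table_for(small_dataset, small_dataset.values)
        rep = iq.class_c_report(table, outlier_threshold=table.w.max() + 1.0)
        assert rep.dist_discrepancy.ks == 0.0
        assert rep.dist_discrepancy.w2 == 0.0
        assert rep.ratio_summary["min"] == rep.ratio_summary["max"] == 1.0
        assert rep.outlier_proportion == 0.0

    def test_constant_imputation_inflates_ratio(self, masked_small):
        truth, mask, incomplete = masked_small
        awful = truth.values.copy()
        awful[mask.mask] = 1e4  # constant far outside the data range
        awful_rep = iq.class_c_report(table_for(truth, awful), 1.0)
        perfect_rep = iq.class_c_report(table_for(truth, truth.values), 1.0)
        assert awful_rep.ratio_summary["mean"] > 10
        assert awful_rep.ratio_summary["mean"] > perfect_rep.ratio_summary["mean"]

    def test_threshold_zero_boundary(self, small_dataset):
        table = table_for(small_dataset, small_dataset.values)
        rep = iq.class_c_report(table, outlier_threshold=0.0)
        assert rep.outlier_proportion == 1.0  # every w_hat > 0 here

    def test_all_zero_baselines_error(self):
        table = iq.SWDistanceTable(
            w=np.zeros((2, 2)), w_hat=np.ones((2, 2)), s=np.ones((2, 2))
        )
        with pytest.raises(ValueError, match="ratios"):
            iq.class_c_report(table, 1.0)


class TestStability:
    def test_identical_tables_zero_between_variance(self, small_dataset):
        t = table_for(small_dataset, small_dataset.values)
        rep = iq.stability_analysis([t, t, t], threshold=1.0)
        assert rep.between_table_variance == 0.0
        assert len(rep.outlier_proportions) == 3

    def test_deterministic_imputer_repeats_identically(self, masked_small):
        truth, mask, incomplete = masked_small
        tables = [
            table_for(truth, iq.impute_mean(incomplete).completions[0])
            for _ in range(3)
        ]
        rep = iq.stability_analysis(tables, threshold=1.0)
        assert rep.between_table_variance == 0.0

    def test_stochastic_imputer_gives_positive_between_variance(
        self, masked_small
    ):
        truth, mask, incomplete = masked_small
        imp = iq.impute_chained_equations(incomplete, m=3, n_iter=2, seed=0)
        tables = [table_for(truth, c) for c in imp.completions]
        rep = iq.stability_analysis(tables, threshold=1.0)
        assert rep.between_table_variance > 0.0

    def test_mismatched_seeds_rejected(self, small_dataset):
        t1 = table_for(small_dataset, small_dataset.values, seed=0)
        t2 = table_for(small_dataset, small_dataset.values, seed=99)
        with pytest.raises(ValueError, match="seeds"):
            iq.stability_analysis([t1, t2], threshold=1.0)

    def test_needs_two_tables(self, small_dataset):
        t = table_for(small_dataset, small_dataset.values)
        with pytest.raises(ValueError):
            iq.stability_analysis([t], threshold=1.0)


def test_monotone_degradation_with_missingness(correlated_bivariate):
    """Mean imputation at growing MCAR rates yields non-decreasing median
    distance ratios w_hat / w."""
    for seed in range(5):
        truth = correlated_bivariate(n=400, rho=0.8, seed=seed)
        dirs = iq.sample_directions(2, 8, seed=seed)
        parts = iq.make_half_partitions(400, 10, seed=seed)
        medians = []
        for rate in (0.1, 0.25, 0.5):
            mask = iq.induce_mcar(truth, rate, seed=seed + 50)
            completed = iq.impute_mean(iq.apply_mask(truth, mask)).completions[0]
            table = iq.sw_distance_table(truth, completed, dirs, parts)
            medians.append(
                iq.class_c_report(table, 1.0).ratio_summary["median"]
            )
        assert medians[0] <= medians[1] <= medians[2]
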