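"""Marginal statistics and their correlation-adjusted counterparts."""

import numpy as np
import pytest

from carsnp import (
    car_scores,
    cat_scores,
    dense_shrunk_power,
    importance_decomposition,
    marginal_correlations,
    standardize_columns,
    t_scores,
)


def _std(y):
    y = np.asarray(y, dtype=float)
    return (y - y.mean()) / y.std(ddof=1)


class TestMarginalCorrelations:
    def test_self_correlation_is_one(self, small_standardized):
        y = small_standardized.values[:, 3]
        r = marginal_correlations(small_standardized, y)
        assert r[3] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response_gives_zero(self):
        x = standardize_columns(np.array([[-1.0], [0.0], [1.0]]))
        y = _std(np.array([1.0, -2.0, 1.0]))
        np.testing.assert_allclose(marginal_correlations(x, y), [0.0], atol=1e-12)

    def test_matches_pearson_formula(self, small_standardized, rng):
        y = _std(rng.standard_normal(small_standardized.n))
        r = marginal_correlations(small_standardized, y)
        expected = [
            np.corrcoef(small_standardized.values[:, j], y)[0, 1]
            for j in range(small_standardized.d)
        ]
        np.testing.assert_allclose(r, expected, atol=1e-10)
        assert np.abs(r).max() <= 1.0

    def test_unstandardized_response_rejected(self, small_standardized):
        with pytest.raises(ValueError, match="standardized"):
            marginal_correlations(small_standardized, np.ones(small_standardized.n) * 2)


class TestTScores:
    def test_textbook_two_sample_value(self):
        x = np.array([[1.0], [2.0], [3.0], [3.0], [4.0], [5.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        # pooled sd 1, so t = -2 / sqrt(2/3)
        np.testing.assert_allclose(t_scores(x, y), [-2 / np.sqrt(2 / 3)], atol=1e-10)

    def test_equal_group_means_give_zero(self):
        x = np.array([[1.0], [3.0], [1.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        np.testing.assert_allclose(t_scores(x, y), [0.0])

    def test_zero_pooled_variance_warns_and_zeroes(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="zero pooled variance"):
            tau = t_scores(x, y)
        np.testing.assert_array_equal(tau, [0.0])

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            t_scores(np.ones((3, 1)), np.array([0, 1, 1]))


class TestCarScores:
    def test_lambda_one_equals_marginal(self, small_standardized, standardized_response):
        y = standardized_response(small_standardized.n)
        t = car_scores(small_standardized, y, lam=1.0)
        np.testing.assert_array_equal(t.adjusted, t.marginal)

    def test_orthogonal_predictors_unchanged_any_lambda(self, standardized_response):
        # empirically orthogonal standardized columns: R_empirical = I
        x = standardize_columns(
            np.column_stack([[-1.0, 0.0, 1.0], np.array([1.0, -2.0, 1.0]) / np.sqrt(3)])
        )
        y = standardized_response(3)
        for lam in (0.05, 0.5, 1.0):
            t = car_scores(x, y, lam=lam)
            np.testing.assert_allclose(t.adjusted, t.marginal, atol=1e-10)

    def test_duplicated_pair_closed_form(self, duplicated_pair, standardized_response):
        lam = 0.1
        y = standardized_response(duplicated_pair.n)
        t = car_scores(duplicated_pair, y, lam=lam)
        rho = t.marginal[0]
        np.testing.assert_allclose(t.adjusted, rho / np.sqrt(2 - lam), atol=1e-12)
        assert abs(t.adjusted[0] - t.adjusted[1]) < 1e-14  # grouping property
        assert abs(t.adjusted[0]) < abs(rho)

    def test_antagonistic_pair_damped(self, standardized_response):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(25)
        x = standardize_columns(np.column_stack([col, -col]))
        y = standardized_response(25)
        lam = 0.1
        t = car_scores(x, y, lam=lam)
        rho = t.marginal[0]
        np.testing.assert_allclose(t.marginal[1], -rho, atol=1e-12)
        np.testing.assert_allclose(
            np.abs(t.adjusted), abs(rho) / np.sqrt(2 - lam), atol=1e-12
        )
        assert np.abs(t.adjusted).max() < abs(rho)

    def test_matches_dense_inverse_sqrt(self, rng, standardized_response):
        for lam in (0.01, 0.1, 0.5, 0.9):
            x = standardize_columns(rng.standard_normal((15, 30)))
            y = standardized_response(15, seed=int(lam * 100))
            t = car_scores(x, y, lam=lam)
            dense = dense_shrunk_power(x, lam, -0.5) @ t.marginal
            np.testing.assert_allclose(t.adjusted, dense, atol=1e-10)

    def test_column_permutation_equivariance(self, small_standardized, standardized_response):
        y = standardized_response(small_standardized.n)
        perm = np.random.default_rng(0).permutation(small_standardized.d)
        x_perm = standardize_columns(
            small_standardized.values[:, perm], small_standardized.column_ids[perm]
        )
        t = car_scores(small_standardized, y, lam=0.1)
        t_perm = car_scores(x_perm, y, lam=0.1)
        np.testing.assert_allclose(t_perm.adjusted, t.adjusted[perm], atol=1e-12)


class TestCatScores:
    @pytest.fixture
    def binary_data(self, rng):
        x = rng.integers(0, 3, size=(40, 8)).astype(float)
        y = np.repeat([0, 1], 20)
        return x, y

    def test_lambda_one_equals_t_scores(self, binary_data):
        x, y = binary_data
        t = cat_scores(x, y, lam=1.0)
        np.testing.assert_array_equal(t.adjusted, t.marginal)
        np.testing.assert_allclose(t.marginal, t_scores(x, y), atol=1e-12)
        assert t.kind == "binary" and t.df == 38

    def test_duplicated_pair_closed_form(self, rng):
        col = rng.integers(0, 3, size=40).astype(float)
        x = np.column_stack([col, col])
        y = np.repeat([0, 1], 20)
        lam = 0.2
        t = cat_scores(x, y, lam=lam)
        np.testing.assert_allclose(
            t.adjusted, t.marginal[0] / np.sqrt(2 - lam), atol=1e-12
        )

    def test_sum_of_squares_is_hotelling_t2(self, binary_data):
        x, y = binary_data
        lam = 0.3
        t = cat_scores(x, y, lam=lam)
        xs = standardize_columns(x)
        dense = dense_shrunk_power(xs, lam, -1.0)
        expected = t.marginal @ dense @ t.marginal
        np.testing.assert_allclose(t.total_importance, expected, atol=1e-10)


class TestScoreTable:
    def test_rank_is_permutation_with_id_tiebreak(self, duplicated_pair, standardized_response):
        t = car_scores(duplicated_pair, standardized_response(30), lam=0.1)
        # identical scores: tie broken by ascending snp_id ("a" before "b")
        assert sorted(t.rank) == [1, 2]
        assert t.rank[list(t.snp_ids).index("a")] == 1

    def test_squared_importance_and_r2_identity(self, small_standardized, standardized_response):
        y = standardized_response(small_standardized.n)
        lam = 0.25
        t = car_scores(small_standardized, y, lam=lam)
        np.testing.assert_array_equal(t.squared_importance, t.adjusted**2)
        dense = dense_shrunk_power(small_standardized, lam, -1.0)
        r2 = t.marginal @ dense @ t.marginal
        np.testing.assert_allclose(t.total_importance, r2, atol=1e-10)

    def test_tsv_round_trip(self, small_standardized, standardized_response, tmp_path):
        t = car_scores(small_standardized, standardized_response(20), lam=0.1)
        path = tmp_path / "scores.tsv"
        t.to_tsv(path)
        back = type(t).from_tsv(path)
        np.testing.assert_allclose(back.adjusted, t.adjusted, atol=1e-12)
        assert back.kind == t.kind and back.lam == t.lam


class TestImportanceDecomposition:
    def test_sums_and_grouping(self, small_standardized, standardized_response):
        t = car_scores(small_standardized, standardized_response(20), lam=0.1)
        groups = {snp: ("g1" if i < 4 else "g2") for i, snp in enumerate(t.snp_ids)}
        dec = importance_decomposition(t, groups)
        assert dec.total == pytest.approx(dec.per_snp.sum(), abs=1e-10)
        assert dec.per_group.sum() == pytest.approx(dec.total, abs=1e-10)
        assert dec.per_group["g1"] == pytest.approx(
            dec.per_snp.iloc[:4].sum(), abs=1e-12
        )

    def test_single_group_carries_total(self, small_standardized, standardized_response):
        t = car_scores(small_standardized, standardized_response(20), lam=1.0)
        dec = importance_decomposition(t, {snp: "all" for snp in t.snp_ids})
        assert dec.per_group["all"] == pytest.approx(dec.total, abs=1e-12)
        # lambda = 1: total is the no-correlation R^2, the sum of r_XY^2
        assert dec.total == pytest.approx(np.sum(t.marginal**2), abs=1e-12)
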