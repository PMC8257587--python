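"""Unit and property tests for the shared statistical primitives."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from permdiff.exceptions import PermdiffError
from permdiff.stats import (
    build_empirical_null, empirical_p, feature_statistic, group_statistics,
    lmr_cutoff_from_null, quantile_normalize, stouffer_combine,
    stouffer_combine_arrays, z_from_p,
)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        np.testing.assert_allclose(quantile_normalize(x), x)

    def test_hand_rank_mean_oracle(self):
        # columns [1,2,3] and [6,4,5]: sorted row means are (2.5, 3.5, 4.5);
        # placement by within-column rank gives col2 = [4.5, 2.5, 3.5]
        x = np.array([[1.0, 6.0], [2.0, 4.0], [3.0, 5.0]])
        out = quantile_normalize(x)
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [4.5, 2.5, 3.5])

    def test_single_column_unchanged(self):
        x = np.array([[5.0], [1.0], [3.0]])
        np.testing.assert_allclose(quantile_normalize(x), x)

    def test_ties_get_mean_of_reference(self):
        x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(x)
        # col1 has tied lowest pair -> both get mean of two lowest refs
        assert out[0, 0] == out[1, 0]

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_dataframe_round_trip(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                          index=list("abcde"), columns=list("xyz"))
        out = quantile_normalize(df)
        assert list(out.index) == list("abcde")
        assert list(out.columns) == list("xyz")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 20), st.integers(2, 5))
    def test_idempotent(self, seed, n, m):
        x = np.random.default_rng(seed).normal(size=(n, m))
        once = quantile_normalize(x)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_share_value_multiset(self, seed):
        x = np.random.default_rng(seed).normal(size=(12, 4))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)


class TestFeatureStatistic:
    def test_lmr_medians_8_vs_4(self):
        fs = feature_statistic(np.log2([8.0, 8.0, 8.0]), np.log2([4.0, 4.0, 4.0]))
        assert fs.LMR == pytest.approx(1.0)
        assert fs.direction == "up"

    def test_identical_groups(self):
        fs = feature_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert fs.T == pytest.approx(0.0)
        assert fs.LMR == pytest.approx(0.0)
        assert fs.direction == "none"

    def test_textbook_pooled_t(self):
        fs = feature_statistic([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert fs.T == pytest.approx(-3.674, abs=5e-4)

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=5), rng.normal(size=7)
        fs = feature_statistic(a, b)
        assert fs.T == pytest.approx(sps.ttest_ind(a, b).statistic)

    def test_zero_variance_flagged_nan(self):
        fs = feature_statistic([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert math.isnan(fs.T)

    def test_too_few_samples_nan(self):
        assert math.isnan(feature_statistic([1.0], [2.0, 3.0]).T)

    def test_group_statistics_agrees_with_scalar(self):
        rng = np.random.default_rng(2)
        data = rng.normal(8, 1, size=(20, 6))
        t, lmr = group_statistics(data, np.arange(3), np.arange(3, 6))
        for i in range(20):
            fs = feature_statistic(data[i, :3], data[i, 3:])
            assert t[i] == pytest.approx(fs.T)
            assert lmr[i] == pytest.approx(fs.LMR)


class TestEmpiricalNull:
    def test_determinism(self):
        data = np.random.default_rng(3).normal(size=(50, 6))
        labels = list("aaabbb")
        n1 = build_empirical_null(data, labels, n_perm=10, seed=42)
        n2 = build_empirical_null(data, labels, n_perm=10, seed=42)
        np.testing.assert_array_equal(n1.null_T, n2.null_T)
        np.testing.assert_array_equal(n1.null_LMR, n2.null_LMR)

    def test_enumerates_when_few_arrangements(self):
        data = np.random.default_rng(4).normal(size=(10, 6))
        with pytest.warns(UserWarning, match="20 distinct"):
            null = build_empirical_null(data, list("aaabbb"), n_perm=100, seed=0)
        assert null.n_perm == 20

    def test_null_pvalues_uniform(self):
        # i.i.d. normal features: empirical p of observed stats ~ U(0,1)
        rng = np.random.default_rng(5)
        data = rng.normal(size=(1000, 10))
        labels = ["a"] * 5 + ["b"] * 5
        null = build_empirical_null(data, labels, n_perm=100, seed=6)
        t, _ = group_statistics(data, np.arange(5), np.arange(5, 10))
        p = empirical_p(t, null.null_T, tail="two")
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_type_i_control(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(2000, 6))
        labels = list("aaabbb")
        null = build_empirical_null(data, labels, n_perm=100, seed=8)
        t, _ = group_statistics(data, np.arange(3), np.arange(3, 6))
        p = empirical_p(t, null.null_T, tail="two")
        for alpha in (0.01, 0.05):
            sd = math.sqrt(alpha * (1 - alpha) / 2000)
            assert abs((p < alpha).mean() - alpha) < 3 * sd

    def test_symmetric_null_cutoff(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(500, 6))
        null = build_empirical_null(data, list("aaabbb"), n_perm=100, seed=1,
                                    lmr_percentiles=(5, 95))
        hi = abs(np.percentile(null.null_LMR, 95))
        assert null.lmr_cutoff == pytest.approx(hi, rel=0.15)

    def test_cutoff_is_mean_of_abs_percentiles(self):
        null_lmr = np.array([-4.0, -2.0, 0.0, 1.0, 3.0])
        lo, hi = np.percentile(null_lmr, [5, 95])
        expected = (abs(lo) + abs(hi)) / 2
        assert lmr_cutoff_from_null(null_lmr, (5, 95)) == pytest.approx(expected)

    def test_bootstrap_scheme_runs(self):
        data = np.random.default_rng(10).normal(size=(50, 6))
        null = build_empirical_null(data, list("aaabbb"),
                                    scheme="sample_resampling",
                                    n_perm=10, seed=0)
        assert null.scheme == "sample_resampling"
        assert null.null_T.size > 0

    def test_single_group_rejected(self):
        data = np.zeros((5, 4))
        with pytest.raises(PermdiffError):
            build_empirical_null(data, list("aaaa"), n_perm=5, seed=0)


class TestEmpiricalP:
    def test_symmetric_null_observed_zero(self):
        assert empirical_p(0.0, [-2, -1, 1, 2], tail="two") == 1.0

    def test_add_one_bound_right(self):
        null = np.arange(99)
        assert empirical_p(1000.0, null, tail="right") == pytest.approx(1 / 100)

    def test_count_by_hand(self):
        # |null| values >= |1.5| are {-2, 2} -> (1+2)/(1+5) = 3/6
        assert empirical_p(1.5, [-2, -1, 0, 1, 2], tail="two") \
            == pytest.approx(3 / 6)

    def test_empty_null_error(self):
        with pytest.raises(PermdiffError):
            empirical_p(1.0, [], tail="two")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_antitone(self, seed):
        rng = np.random.default_rng(seed)
        null = rng.normal(size=50)
        obs = np.sort(rng.normal(size=10))
        p_right = empirical_p(obs, null, tail="right")
        assert np.all(np.diff(p_right) <= 0)
        p_two = empirical_p(np.sort(np.abs(obs)), null, tail="two")
        assert np.all(np.diff(p_two) <= 0)


class TestStouffer:
    def test_both_p_one(self):
        c = stouffer_combine(1.0, 1.0, 1, 1)
        assert c.z_T == pytest.approx(0.0)
        assert c.overall_p == pytest.approx(1.0)

    def test_same_direction_oracle(self):
        # normal CDF oracle: z = isf(0.05/2) = 1.95996,
        # z_comb = 2 z / sqrt(2) = 2.77181, overall = 2 sf(z_comb) = 0.005575
        c = stouffer_combine(0.05, 0.05, 1, 1)
        assert c.z_T == pytest.approx(1.959964, abs=1e-5)
        assert c.overall_p == pytest.approx(0.0055746, abs=1e-6)

    def test_opposite_directions_cancel(self):
        c = stouffer_combine(0.05, 0.05, 1, -1)
        assert c.overall_p == pytest.approx(1.0)

    def test_monotone_in_components(self):
        p1 = stouffer_combine(0.01, 0.05, 1, 1).overall_p
        p2 = stouffer_combine(0.02, 0.05, 1, 1).overall_p
        assert p1 < p2

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            c = stouffer_combine(0.0, 0.5, 1, 1, n_perm=99)
        assert 0 < c.overall_p < 1

    def test_zero_p_without_nperm_raises(self):
        with pytest.raises(ValueError):
            stouffer_combine(0.0, 0.5, 1, 1)

    def test_closed_form_agreement(self):
        # 1000 random (p1, p2, direction) triples vs 2(1 - Phi(|z1+z2|/sqrt 2))
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p1, p2 = rng.uniform(1e-6, 1.0, size=2)
            d1, d2 = rng.choice([-1.0, 1.0], size=2)
            c = stouffer_combine(p1, p2, d1, d2)
            expected = 2 * sps.norm.sf(abs(c.z_T + c.z_LMR) / math.sqrt(2))
            assert c.overall_p == pytest.approx(min(expected, 1.0), abs=1e-9)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(12)
        p1 = rng.uniform(0.001, 1, size=20)
        p2 = rng.uniform(0.001, 1, size=20)
        d1 = rng.choice([-1, 1], size=20)
        d2 = rng.choice([-1, 1], size=20)
        vec = stouffer_combine_arrays(p1, p2, d1, d2)
        for i in range(20):
            assert vec[i] == pytest.approx(
                stouffer_combine(p1[i], p2[i], d1[i], d2[i]).overall_p)


class TestZFromP:
    def test_median(self):
        assert z_from_p(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_normal_oracle(self):
        assert z_from_p(0.05) == pytest.approx(1.645, abs=5e-4)
        assert z_from_p(0.001) == pytest.approx(3.090, abs=5e-4)

    def test_strictly_decreasing(self):
        ps = np.linspace(0.01, 0.99, 25)
        assert np.all(np.diff(z_from_p(ps)) < 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            z_from_p(bad)
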