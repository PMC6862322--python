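"""statcore: exact rank-sum enumeration, t tests, HL intervals, omnibus tests."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from retinaquant import statcore
from retinaquant._exceptions import InsufficientDataError, ValidationError


def brute_force_ranksum_p(a, b):
    """Independent oracle: direct enumeration over value subsets (not ranks)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    sums = [sum(c) for c in combinations(ranks, n_a)]
    n = len(sums)
    p_le = sum(1 for s in sums if s <= w_obs + 1e-9) / n
    p_ge = sum(1 for s in sums if s >= w_obs - 1e-9) / n
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonExact:
    def test_complete_separation_4v4(self):
        # Minimum attainable two-sided p for 4 vs 4: 2/70
        res = statcore.wilcoxon_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.p_value == pytest.approx(2 / 70)
        assert round(res.p_value, 4) == 0.0286

    def test_interior_rank_pattern(self):
        # one group at pooled ranks {1,2,3,6}: p = 2 * (4/70) = 8/70
        res = statcore.wilcoxon_exact([1, 2, 3, 6], [4, 5, 7, 8])
        assert res.p_value == pytest.approx(8 / 70)
        assert round(res.p_value, 4) == 0.1143

    def test_all_tied(self):
        res = statcore.wilcoxon_exact([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_matches_scipy_exact_for_tie_free(self):
        rng = np.random.default_rng(0)
        for n_a in range(2, 7):
            for n_b in range(2, 7):
                a = rng.normal(size=n_a)
                b = rng.normal(0.5, size=n_b)
                ours = statcore.wilcoxon_exact(a, b).p_value
                ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
                assert ours == pytest.approx(ref, abs=1e-12), (n_a, n_b)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.integers(0, 4, size=4).astype(float)
            b = rng.integers(0, 4, size=5).astype(float)
            assert statcore.wilcoxon_exact(a, b).p_value == pytest.approx(
                brute_force_ranksum_p(a, b)
            )

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=5), rng.normal(size=6)
        assert statcore.wilcoxon_exact(a, b).p_value == pytest.approx(
            statcore.wilcoxon_exact(b, a).p_value
        )

    def test_minimum_achievable_p(self):
        for n_a, n_b in [(3, 3), (4, 4), (2, 5)]:
            a = np.arange(n_a, dtype=float)
            b = np.arange(n_b, dtype=float) + 100
            assert statcore.wilcoxon_exact(a, b).p_value == pytest.approx(
                2 / math.comb(n_a + n_b, n_a)
            )

    def test_empty_sample_raises(self):
        with pytest.raises(ValidationError):
            statcore.wilcoxon_exact([], [1, 2])

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        res = statcore.wilcoxon_exact(rng.normal(size=15), rng.normal(size=15))
        assert res.method == "wilcoxon_normal_approx"


class TestTTests:
    def test_textbook_pair(self):
        # pooled t for {1,2,3,4} vs {2,3,4,5}: |t| = 1 / sqrt(5/6) = 1.0954, df 6
        res = statcore.two_sample_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert abs(res.statistic) == pytest.approx(1.0954, abs=1e-4)
        assert res.df == 6
        assert res.estimate == pytest.approx(1.0)

    def test_identical_samples(self):
        res = statcore.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.estimate == 0.0

    def test_summary_matches_raw(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=12)
        raw = statcore.two_sample_t(a, b)
        summ = statcore.t_from_summary(
            a.mean(), a.std(ddof=1), 10, b.mean(), b.std(ddof=1), 12
        )
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.ci_low == pytest.approx(summ.ci_low, abs=1e-10)

    def test_published_total_thickness_row(self):
        res = statcore.t_from_summary(252.4, 51.5, 21, 149.0, 51.0, 21)
        assert res.p_value < 0.0001
        assert res.estimate == pytest.approx(-103.4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(0.5, size=9)
        res = statcore.two_sample_t(a, b)
        ref = stats.ttest_ind(a, b)
        assert res.p_value == pytest.approx(ref.pvalue)
        welch = statcore.two_sample_t(a, b, pooled=False)
        ref_w = stats.ttest_ind(a, b, equal_var=False)
        assert welch.p_value == pytest.approx(ref_w.pvalue)

    def test_zero_variance_both_raises(self):
        with pytest.raises(ValidationError):
            statcore.two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestHodgesLehmann:
    def test_hand_enumerated(self):
        # pairwise diffs b - a: {3, 6, 2, 5} -> median 4.0
        res = statcore.hodges_lehmann([1, 2], [4, 7])
        assert res.estimate == pytest.approx(4.0)
        assert res.ci_low <= res.estimate <= res.ci_high

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.floats(-20, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_equivariance(self, values, delta):
        a = np.asarray(values)
        res = statcore.hodges_lehmann(a, a + delta)
        assert res.estimate == pytest.approx(delta, abs=1e-9)

    def test_estimate_is_median_of_pairwise_diffs(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=5), rng.normal(1, size=7)
        diffs = [bi - ai for bi in b for ai in a]
        assert statcore.hodges_lehmann(a, b).estimate == pytest.approx(np.median(diffs))

    def test_exact_coverage_4v4(self):
        # nominal 95 %; exact interval at n=4/4 achieves 1 - 2/70
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.normal(size=4)
            b = rng.normal(size=4)  # true shift = 0
            res = statcore.hodges_lehmann(a, b)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert hits / n_rep >= 0.94
        assert statcore.hodges_lehmann([1, 2, 3, 4], [1, 2, 3, 4]).ci_level >= 0.95


class TestKSNormality:
    def test_exponential_rejected(self):
        rng = np.random.default_rng(8)
        assert statcore.ks_normality(rng.exponential(size=1000), seed=0) < 0.001

    def test_normal_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = [
            statcore.ks_normality(rng.standard_normal(60), n_sims=400, seed=i)
            for i in range(120)
        ]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValidationError):
            statcore.ks_normality([3.0, 3.0, 3.0, 3.0])

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            statcore.ks_normality([1.0, 2.0, 3.0])

    def test_seed_determinism(self):
        x = np.random.default_rng(10).standard_normal(30)
        assert statcore.ks_normality(x, seed=5) == statcore.ks_normality(x, seed=5)


class TestOmnibus:
    def test_anova_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        overall, pairs = statcore.anova_bonferroni([g, g, g])
        assert overall.p_value > 0.5
        assert all(res.p_value == 1.0 for _, _, res in pairs)

    def test_bonferroni_is_m_times_raw(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=6), rng.normal(2, size=6)
        raw = statcore.two_sample_t(a, b).p_value
        _, pairs = statcore.anova_bonferroni([a, b], family_m=8)
        assert pairs[0][2].p_value == pytest.approx(min(1.0, 8 * raw))
        assert pairs[0][2].family_m == 8

    def test_anova_type1_calibration(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            groups = [rng.normal(size=6) for _ in range(3)]
            overall, _ = statcore.anova_bonferroni(groups)
            rejections += overall.p_value < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_friedman_identical_treatments(self):
        data = np.tile([[1.0], [2.0], [3.0]], (1, 4))
        overall, pairs = statcore.friedman(data)
        assert overall.statistic == 0.0
        assert overall.p_value == 1.0
        assert all(res.p_value == 1.0 for _, _, res in pairs)

    def test_friedman_hand_computed_3x4(self):
        # blocks x treatments; within-block ranks are untied by construction
        data = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [1.0, 3.0, 2.0, 4.0],
                [2.0, 1.0, 3.0, 4.0],
            ]
        )
        # rank sums per treatment: [4, 6, 8, 12]
        n, k = 3, 4
        expected = 12.0 / (n * k * (k + 1)) * (16 + 36 + 64 + 144) - 3 * n * (k + 1)
        overall, _ = statcore.friedman(data)
        assert overall.statistic == pytest.approx(expected)
        ref = stats.friedmanchisquare(*data.T)
        assert overall.statistic == pytest.approx(ref.statistic)

    def test_friedman_incomplete_blocks(self):
        data = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValidationError):
            statcore.friedman(data)


class TestDecisionTree:
    def test_small_samples_go_nonparametric(self):
        res = statcore.compare([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(2 / 70)
        assert np.isfinite(res.estimate)  # Hodges-Lehmann attached

    def test_large_normal_samples_go_parametric(self):
        rng = np.random.default_rng(13)
        res = statcore.compare(rng.normal(size=40), rng.normal(size=40))
        assert res.method == "student_t"

    def test_large_nonnormal_samples_stay_nonparametric(self):
        rng = np.random.default_rng(14)
        res = statcore.compare(rng.exponential(size=200), rng.exponential(size=200))
        assert res.method == "wilcoxon_normal_approx"


class TestTypeICalibration:
    @pytest.mark.parametrize("method", ["t", "wilcoxon"])
    def test_alpha_level_held(self, method):
        rng = np.random.default_rng(15)
        n_sims = 1000
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            if method == "t":
                p = statcore.two_sample_t(a, b).p_value
            else:
                p = statcore.wilcoxon_exact(a, b).p_value
            rejections += p < 0.05
        # exact rank-sum is conservative at n=6/6 (discrete support)
        assert rejections / n_sims <= 0.07
        if method == "t":
            assert rejections / n_sims >= 0.03
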