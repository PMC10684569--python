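from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from osseosurf.stats import (
    bonferroni,
    describe,
    kruskal_wallis,
    mann_whitney,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


# -- independent enumeration oracles (test-side implementations) ---------

def oracle_wilcoxon_p(diffs):
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    mu = len(d) * (len(d) + 1) / 4.0
    w_obs = ranks[d > 0].sum()
    hits = total = 0
    for signs in product([False, True], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        hits += abs(w - mu) >= abs(w_obs - mu) - 1e-12
        total += 1
    return hits / total


def oracle_mannwhitney_p(a, b):
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2.0
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return hits / total


class TestDescribe:
    def test_even_sample_median(self):
        assert describe([1, 2, 3, 4]).median == pytest.approx(2.5)

    def test_constant_iqr_zero(self):
        assert describe([7.0] * 10).iqr == 0.0

    def test_uniform_iqr(self):
        """IQR of uniform(0,1) is 0.5 (within 2% at n = 10,000)."""
        rng = np.random.default_rng(0)
        s = describe(rng.uniform(0, 1, 10_000))
        assert abs(s.iqr - 0.5) <= 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestWilcoxon:
    def test_three_positive_differences(self):
        """(1,2,3): both tails of the 2³ sign patterns → p = 0.25 exactly."""
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(0.25)
        assert r.method == "exact-enumeration"

    def test_symmetric_differences_give_p_one(self):
        r = wilcoxon_signed_rank([-1.0, 1.0, -2.0, 2.0])
        assert r.p_value == pytest.approx(1.0)

    def test_all_zeros_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_zero_dropping_recorded(self):
        r = wilcoxon_signed_rank([0.0, 1.0, -2.0, 3.0])
        assert "1 zero" in r.notes
        assert r.n == (3,)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(0.3, 1.0, n), 1)
        d = d[d != 0]
        if len(d) < 3:
            return
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            oracle_wilcoxon_p(d), abs=1e-12
        )

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            d = rng.normal(0.5, 1.0, 10)  # continuous → no ties
            ours = wilcoxon_signed_rank(d).p_value
            ref = sps.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.2, 1.0, 60)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=False).pvalue
        assert ours.method == "normal-approx-tie-corrected"
        assert ours.p_value == pytest.approx(ref, abs=1e-9)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        """a=(1,2) vs b=(3,4): U = 0 and exact two-sided p = 1/3."""
        r = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0 / 3.0)

    def test_identical_multisets_give_p_one(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 6))
        a = np.round(rng.normal(0, 1, n_a), 1)
        b = np.round(rng.normal(0.5, 1, n_b), 1)
        assert mann_whitney(a, b).p_value == pytest.approx(
            oracle_mannwhitney_p(a, b), abs=1e-12
        )

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
            ours = mann_whitney(a, b).p_value
            ref = sps.mannwhitneyu(a, b, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_sample_approximation_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 30), rng.normal(0.3, 1, 25)
        ours = mann_whitney(a, b).p_value
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        r = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0.0)

    def test_hand_ranked_oracle(self):
        """(1,2), (10,11), (20,21): ranks 1..6, H by the rank-sum formula."""
        groups = [[1.0, 2.0], [10.0, 11.0], [20.0, 21.0]]
        # ranks: (1,2), (3,4), (5,6); mean ranks 1.5, 3.5, 5.5; N=6
        h_hand = 12.0 / (6 * 7) * (2 * (1.5 - 3.5) ** 2 + 2 * 0.0 + 2 * (5.5 - 3.5) ** 2)
        r = kruskal_wallis(groups)
        assert r.statistic == pytest.approx(h_hand, abs=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(i * 0.5, 1, 8) for i in range(4)]
        ours = kruskal_wallis(groups)
        ref_h, ref_p = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref_h, abs=1e-9)
        assert ours.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_ties_corrected_matches_scipy(self):
        groups = [[1, 1, 2, 3], [2, 2, 3, 4], [1, 4, 4, 5]]
        ours = kruskal_wallis(groups)
        ref_h, _ = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref_h, abs=1e-9)

    def test_degenerate_constant_data(self):
        r = kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])
        assert r.statistic == 0.0
        assert "degenerate" in r.notes

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(i, 1, 7) for i in range(3)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestBonferroni:
    def test_scaling_and_cap(self):
        out = bonferroni([0.01, 0.5], m=3)
        assert out[0] == pytest.approx(0.03)
        assert out[1] == 1.0

    def test_m_smaller_than_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestShapiroWilk:
    def test_normal_scores_give_w_near_one(self):
        """Expected normal order statistics make W approach 1."""
        scores = sps.norm.ppf((np.arange(1, 201) - 0.375) / (200 + 0.25))
        r = shapiro_wilk(scores)
        assert r.statistic >= 0.999

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([3.0] * 10)

    def test_bimodal_sample_rejects_normality(self):
        v = np.array([-10.0, 10.0] * 15) + np.linspace(0, 0.1, 30)
        assert shapiro_wilk(v).p_value < 0.01

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
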