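"""Nonparametric statistics: diagnostics, rank tests, correlation, comparisons."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from engagekit import (
    CHARACTERISTICS,
    DegenerateDistributionError,
    UndefinedInputError,
    compare_by_characteristics,
    default_config,
    diagnose_distribution,
    generate_cohort,
    kruskal_wallis,
    mann_whitney,
    median_iqr,
    score_cohort,
    spearman,
)


def _brute_force_u(a, b):
    """Exhaustive cross-pair count: #(a > b) + half ties."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def _mid_ranks(v):
    """Mid-ranks built explicitly: average of the 1-based sorted positions of
    each tied block."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


class TestDiagnostics:
    def test_normal_samples_usually_flagged_normal(self):
        rng = np.random.default_rng(100)
        flags = [
            diagnose_distribution(rng.normal(size=1000)).normality_flag for _ in range(100)
        ]
        assert np.mean(flags) >= 0.95

    def test_right_skewed_sample_flagged_nonnormal(self):
        rng = np.random.default_rng(7)
        diag = diagnose_distribution(np.exp(rng.normal(size=800)))
        assert diag.skewness > 1 and not diag.normality_flag

    def test_skewness_negates_under_reflection(self):
        rng = np.random.default_rng(3)
        v = rng.gamma(2.0, size=200)
        d1 = diagnose_distribution(v)
        d2 = diagnose_distribution(2 * v.mean() - v)
        assert d2.skewness == pytest.approx(-d1.skewness)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            diagnose_distribution(np.ones(50))

    def test_small_sample_rejected(self):
        with pytest.raises(UndefinedInputError):
            diagnose_distribution([1.0, 2.0, 3.0])


class TestMedianIQR:
    def test_simple_median(self):
        assert median_iqr([1, 2, 3]).median == 2.0

    def test_constant_vector_zero_width(self):
        assert median_iqr([5.0] * 9).width == 0.0

    def test_quartile_order(self):
        m = median_iqr(np.arange(101))
        assert m.q1 <= m.median <= m.q3 and m.width == m.q3 - m.q1


class TestMannWhitney:
    def test_identical_multisets_give_null_result(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.z == 0.0 and res.p_value == 1.0

    def test_u_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            a = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
            res = mann_whitney(a, b)
            assert res.u == pytest.approx(_brute_force_u(a, b))

    def test_agrees_with_scipy_u(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=30), rng.normal(0.4, size=25)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, use_continuity=True, method="asymptotic")
        assert res.u == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_large_shift_separates(self):
        rng = np.random.default_rng(1)
        res = mann_whitney(rng.normal(10, 1, 40), rng.normal(0, 1, 40))
        assert res.p_value < 0.001 and res.z > 0

    def test_u_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mann_whitney(a, b).u == pytest.approx(mann_whitney(np.exp(a), np.exp(b)).u)

    def test_u_min_convention(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6, 7])
        assert res.u == 0.0 and res.u_min == 0.0
        res2 = mann_whitney([4, 5, 6, 7], [1, 2, 3])
        assert res2.u == 12.0 and res2.u_min == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(UndefinedInputError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.h == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_observations_zero_h(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5]])
        assert res.h == 0.0 and res.p_value == 1.0

    def test_matches_hand_computed_rank_formula(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 2.0, 8.0], [4.0, 9.0, 9.0, 6.0]]
        pooled = np.concatenate(groups)
        ranks = _mid_ranks(pooled)
        n = len(pooled)
        sizes = [len(g) for g in groups]
        split = np.split(ranks, np.cumsum(sizes)[:-1])
        h = 12.0 / (n * (n + 1)) * sum(
            len(g) * (r.mean() - (n + 1) / 2.0) ** 2 for g, r in zip(groups, split)
        )
        _, ties = np.unique(pooled, return_counts=True)
        h /= 1.0 - (ties**3 - ties).sum() / (n**3 - n)
        assert kruskal_wallis(groups).h == pytest.approx(h)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(77)
        reject = 0
        reps = 500
        for _ in range(reps):
            groups = np.split(rng.uniform(size=60), [15, 30, 45])
            if kruskal_wallis(groups).p_value < 0.05:
                reject += 1
        rate = reject / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 1.96 * se

    def test_invariant_under_group_relabeling(self):
        groups = [[1, 5, 3], [2, 2, 9], [7, 4]]
        assert kruskal_wallis(groups).h == pytest.approx(kruskal_wallis(groups[::-1]).h)

    def test_two_groups_rejected(self):
        with pytest.raises(UndefinedInputError):
            kruskal_wallis([[1, 2], [3, 4]])


class TestSpearman:
    def test_monotone_function_perfect_correlation(self):
        x = np.array([1.0, 2.5, 4.0, 7.0, 9.0])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_tied_instance_matches_rank_constructed_pearson(self):
        x = np.array([1, 1, 2, 3, 3, 3, 4, 5, 5, 6], dtype=float)
        y = np.array([2, 3, 3, 1, 5, 5, 4, 6, 6, 2], dtype=float)
        expected = np.corrcoef(_mid_ranks(x), _mid_ranks(y))[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert spearman(x, y).rho == pytest.approx(spearman(np.exp(x), y**3).rho)

    def test_constant_variable_undefined(self):
        with pytest.raises(UndefinedInputError):
            spearman([1, 1, 1], [1, 2, 3])


@pytest.fixture(scope="module")
def scored():
    cohort = generate_cohort(default_config(), seed=17)
    return cohort, score_cohort(cohort)


class TestCompareByCharacteristics:
    def test_all_characteristics_and_metrics_covered(self, scored):
        cohort, summaries = scored
        results = compare_by_characteristics(summaries, cohort.profiles)
        assert len(results) == len(CHARACTERISTICS) * 2
        labels = {(r.characteristic, r.statistic_label) for r in results}
        assert ("self_help", "U/z") in labels  # binary -> Mann-Whitney
        assert ("age_group", "H") in labels  # 4 levels -> Kruskal-Wallis

    def test_group_sizes_sum_to_cohort(self, scored):
        cohort, summaries = scored
        for r in compare_by_characteristics(summaries, cohort.profiles):
            assert r.n_total == len(summaries)
            assert 0.0 <= r.p_value <= 1.0

    def test_empty_category_dropped_with_warning(self, scored):
        cohort, summaries = scored
        profiles = cohort.profiles.copy()
        profiles.loc[profiles["economic_status"] == "high", "economic_status"] = "middle"
        with pytest.warns(UserWarning, match="empty category 'high'"):
            results = compare_by_characteristics(
                summaries, profiles, characteristics={"economic_status": CHARACTERISTICS["economic_status"]}
            )
        assert all(r.statistic_label == "U/z" for r in results)

    def test_no_adjustment_by_default_and_optional_holm(self, scored):
        cohort, summaries = scored
        plain = compare_by_characteristics(summaries, cohort.profiles)
        assert all(r.p_adjusted is None for r in plain)
        adj = compare_by_characteristics(summaries, cohort.profiles, adjust="holm")
        assert all(r.p_adjusted is not None and r.p_adjusted >= r.p_value - 1e-12 for r in adj)

    def test_injected_selfhelp_effect_yields_smallest_p_usually(self):
        """With a strong injected self-help engagement shift, the self-help
        comparison should have the smallest p among characteristics in the
        majority of replicates."""
        cfg = default_config(selfhelp_effect=0.12)
        wins = 0
        reps = 100
        for r in range(reps):
            cohort = generate_cohort(cfg, seed=50_000 + r)
            summaries = score_cohort(cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = compare_by_characteristics(summaries, cohort.profiles)
            pvals = {
                res.characteristic: res.p_value
                for res in results
                if res.metric == "engagement_index"
            }
            if min(pvals, key=pvals.get) == "self_help":
                wins += 1
        assert wins > reps / 2
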