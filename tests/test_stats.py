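"""Morphometric indices and the cohort statistics battery.

Rank-test results are checked against independent brute-force oracles:
full label-assignment enumeration for Mann-Whitney, hypergeometric
enumeration for Fisher's exact test, and the hand rank-sum formula for
Kruskal-Wallis.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfoi import stats


def mann_whitney_exact_oracle(a, b):
    """Two-sided exact p by enumerating all C(n+m, n) group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)

    def u_stat(group_a, group_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
        )

    observed = u_stat(a, b)
    mean_u = len(a) * len(b) / 2.0
    obs_dev = abs(observed - mean_u)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        in_a = set(combo)
        ga = [pooled[i] for i in in_a]
        gb = [pooled[i] for i in range(len(pooled)) if i not in in_a]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= obs_dev - 1e-12:
            count += 1
    return count / total


def fisher_exact_oracle(table):
    """Two-sided p summing hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-12)
    )


class TestMorphometricIndices:
    def test_evans_index_ratios(self):
        assert stats.evans_index(35.0, 140.0) == pytest.approx(0.25)
        assert stats.evans_index(51.8, 140.0) == pytest.approx(0.37)
        assert stats.evans_index(100.0, 100.0) == 1.0

    def test_z_evans_and_bvr(self):
        assert stats.z_evans_index(36.0, 150.0) == pytest.approx(0.24)
        assert stats.bvr(42.0, 20.0) == pytest.approx(2.1)

    def test_nonpositive_inputs_rejected(self):
        for fn in (stats.evans_index, stats.z_evans_index, stats.bvr):
            with pytest.raises(ValueError):
                fn(0.0, 10.0)
            with pytest.raises(ValueError):
                fn(10.0, -1.0)

    def test_callosal_angle_right_angle(self):
        assert stats.callosal_angle([0, 1], [0, 0], [1, 0]) == pytest.approx(90.0)

    def test_callosal_angle_collinear_rejected(self):
        with pytest.raises(ValueError):
            stats.callosal_angle([0, 0], [1, 1], [2, 2])
        with pytest.raises(ValueError):
            stats.callosal_angle([1, 1], [1, 1], [2, 2])


class TestPearsonWithCI:
    def test_published_headline_interval(self):
        res = stats.pearson_ci_from_r(0.76, 171)
        assert round(res.ci_low, 2) == 0.69
        assert round(res.ci_high, 2) == 0.82

    def test_null_interval_symmetric(self):
        res = stats.pearson_ci_from_r(0.0, 171)
        half = np.tanh(1.96 / np.sqrt(168))
        assert res.ci_low == pytest.approx(-half, abs=1e-12)
        assert res.ci_high == pytest.approx(half, abs=1e-12)
        assert round(res.ci_high, 3) == 0.150

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = stats.pearson_with_ci(x, 2.0 * x)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-30

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.pearson_with_ci([1.0] * 6, [1, 2, 3, 4, 5, 6])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=-0.95, max_value=0.95),
        st.integers(min_value=5, max_value=500),
    )
    def test_interval_contains_r_and_shrinks_with_n(self, r, n):
        res = stats.pearson_ci_from_r(r, n)
        wider = stats.pearson_ci_from_r(r, max(4, n // 2))
        assert res.ci_low <= res.r <= res.ci_high
        assert (res.ci_high - res.ci_low) <= (wider.ci_high - wider.ci_low) + 1e-12


class TestGroupCompare:
    def test_mann_whitney_exact_separated_groups(self):
        _, p = stats.group_compare({"a": [1, 2, 3], "b": [4, 5, 6]}, "mann_whitney")
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mann_whitney_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=6).round(2)
        b = rng.normal(0.8, 1.0, size=5).round(2)
        while np.intersect1d(a, b).size:  # oracle assumes untied samples
            b = rng.normal(0.8, 1.0, size=5).round(2)
        _, p = stats.group_compare({"a": a, "b": b}, "mann_whitney")
        assert p == pytest.approx(mann_whitney_exact_oracle(a, b), abs=1e-12)

    def test_mann_whitney_normal_approximation_close_for_large_groups(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=31)
        b = rng.normal(0.3, 1.0, size=33)
        from scipy.stats import mannwhitneyu
        exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        _, p = stats.group_compare({"a": a, "b": b}, "mann_whitney")
        assert p == pytest.approx(exact, abs=0.02)

    def test_fisher_exact_diagonal_table(self):
        _, p = stats.group_compare([[2, 0], [0, 2]], "fisher_exact")
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("table", [[[2, 0], [0, 2]], [[5, 1], [2, 6]],
                                       [[3, 3], [3, 3]], [[8, 2], [1, 7]]])
    def test_fisher_exact_matches_hypergeometric_oracle(self, table):
        _, p = stats.group_compare(table, "fisher_exact")
        assert p == pytest.approx(fisher_exact_oracle(table), abs=1e-9)

    def test_kruskal_wallis_hand_computed(self):
        # ranks 1..6, rank sums 3, 7, 11: H = 12/(6*7) * sum(R^2/2) - 3*7
        stat, _ = stats.group_compare(
            {"a": [1, 2], "b": [3, 4], "c": [5, 6]}, "kruskal_wallis"
        )
        assert stat == pytest.approx(4.571, abs=5e-4)

    def test_kruskal_two_groups_orders_like_mann_whitney(self):
        rng = np.random.default_rng(3)
        p_kw, p_mw = [], []
        for shift in (0.0, 0.5, 1.5):
            a = rng.normal(size=20)
            b = rng.normal(shift, 1.0, size=20)
            p_kw.append(stats.group_compare({"a": a, "b": b}, "kruskal_wallis")[1])
            p_mw.append(stats.group_compare({"a": a, "b": b}, "mann_whitney")[1])
        assert np.argsort(p_kw).tolist() == np.argsort(p_mw).tolist()

    def test_group_relabeling_invariance(self):
        data = {"x": [1.0, 2.0, 5.0], "y": [3.0, 4.0, 6.0]}
        renamed = {"group_b": data["x"], "group_a": data["y"]}
        assert stats.group_compare(data, "mann_whitney")[1] == pytest.approx(
            stats.group_compare(renamed, "mann_whitney")[1]
        )

    def test_chi_square_runs_on_table(self):
        stat, p = stats.group_compare([[30, 15], [21, 15]], "chi_square")
        assert stat >= 0 and 0 <= p <= 1

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            stats.group_compare([[1, 2, 3], [4, 5, 6]], "fisher_exact")
        with pytest.raises(ValueError):
            stats.group_compare({"only": [1, 2]}, "mann_whitney")
        with pytest.raises(ValueError):
            stats.group_compare({"a": [1], "b": [2]}, "nonsense")


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_correlation(self):
        x = pd.DataFrame({"evans": np.arange(10.0)}, index=range(10))
        y = pd.DataFrame({"roi": np.arange(10.0)}, index=range(10))
        out = stats.correlation_matrix(x, y)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        n = 500
        x = pd.DataFrame({"evans": rng.normal(size=n)}, index=range(n))
        y = pd.DataFrame({"roi": rng.normal(size=n)}, index=range(n))
        out = stats.correlation_matrix(x, y)
        assert abs(out.loc[0, "r"]) < 0.12

    def test_pairwise_complete_n_reported(self):
        x = pd.DataFrame({"evans": [1.0, 2, 3, 4, 5, np.nan]}, index=range(6))
        y = pd.DataFrame({"roi": [2.0, 4, 6, 8, np.nan, 12]}, index=range(6))
        out = stats.correlation_matrix(x, y)
        assert out.loc[0, "n"] == 4
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_insufficient_pairs_flagged_missing(self):
        x = pd.DataFrame({"evans": [1.0, 2, np.nan, np.nan, np.nan]}, index=range(5))
        y = pd.DataFrame({"roi": [1.0, 2, 3, 4, 5]}, index=range(5))
        out = stats.correlation_matrix(x, y)
        assert np.isnan(out.loc[0, "r"]) and out.loc[0, "n"] == 2

    def test_benjamini_hochberg_monotone(self):
        p = [0.001, 0.01, 0.04, 0.5]
        adj = stats.benjamini_hochberg(p)
        assert np.all(adj >= p)
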