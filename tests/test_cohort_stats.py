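"""Clinical association statistics: Spearman (plain/partial/exact), ANOVA,
Fisher exact, paired change, Ward clustering, EULAR bands."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from synopath.cohort_stats import (
    adjust_family,
    anova_bonferroni,
    eular_response,
    fisher_exact_2x2,
    paired_change_test,
    spearman_adjusted,
    ward_cluster,
)


class TestSpearman:
    def test_monotone_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = spearman_adjusted(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = spearman_adjusted(x, y)
        ref = stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_oracle(self):
        """rho = 0.7 on the tied 5-point example; exact p equals brute-force
        enumeration over all 120 rank permutations."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([5.0, 6, 7, 8, 7])
        res = spearman_adjusted(x, y, exact=True)
        # tied-rank rho = 8/sqrt(95), cross-checked against scipy
        rho = float(stats.spearmanr(x, y).statistic)
        assert rho == pytest.approx(8 / np.sqrt(95), abs=1e-12)
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        from itertools import permutations

        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        count = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho) - 1e-12 for perm in permutations(ry)
        )
        assert res.p_value == pytest.approx(count / 120)

    def test_adjusted_equals_unadjusted_single_category(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        plain = spearman_adjusted(x, y)
        adj = spearman_adjusted(x, y, joint=["wrist"] * 30)
        assert adj.statistic == pytest.approx(plain.statistic, abs=1e-12)
        assert adj.p_value == pytest.approx(plain.p_value, rel=1e-9)

    def test_adjustment_removes_joint_confounding(self, rng):
        # x and y share no signal within joints but both shift by joint
        joint = np.repeat(["a", "b"], 40)
        offset = np.where(joint == "a", 3.0, -3.0)
        x = offset + rng.normal(size=80)
        y = offset + rng.normal(size=80)
        plain = spearman_adjusted(x, y)
        adj = spearman_adjusted(x, y, joint=joint)
        assert plain.statistic > 0.5
        assert abs(adj.statistic) < 0.3

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=12)
        a = spearman_adjusted(x, y)
        b = spearman_adjusted(np.exp(x / 3), y**3)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_insufficient_or_constant_inputs(self):
        with pytest.raises(ValueError):
            spearman_adjusted([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_adjusted([1, 1, 1, 1], [1, 2, 3, 4])


class TestAnova:
    def test_identical_groups(self):
        vals = np.array([1.0, 2, 1, 2, 1, 2])
        groups = ["a", "a", "b", "b", "c", "c"]
        overall, pairwise = anova_bonferroni(vals, groups)
        assert overall.statistic == 0.0 and overall.p_value == 1.0
        assert all(p.p_value == 1.0 for p in pairwise)

    def test_textbook_formula_oracle(self):
        vals = np.array([2.0, 4, 6, 8, 10, 12])
        groups = ["a", "a", "b", "b", "c", "c"]
        overall, pairwise = anova_bonferroni(vals, groups)
        # hand computation: SSB = 2*(3-7)^2 + 2*(7-7)^2 + 2*(11-7)^2 = 64,
        # SSW = 3 * 2 = 6; F = (64/2)/(6/3) = 16
        assert overall.statistic == pytest.approx(16.0, abs=1e-10)
        ref = stats.f_oneway(vals[:2], vals[2:4], vals[4:])
        assert overall.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert overall.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        # Bonferroni: pairwise p = min(1, 3 * plain t p)
        t_ref = stats.ttest_ind(vals[:2], vals[2:4], equal_var=True)
        assert pairwise[0].p_value == pytest.approx(min(1.0, 3 * t_ref.pvalue), abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        vals = rng.normal(size=18)
        groups = np.repeat(["a", "b", "c"], 6)
        p1 = anova_bonferroni(vals, groups)[0].p_value
        relabeled = np.array({"a": "c", "b": "a", "c": "b"}[g] for g in groups)
        relabeled = np.array([{"a": "c", "b": "a", "c": "b"}[g] for g in groups])
        p2 = anova_bonferroni(vals, relabeled)[0].p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            anova_bonferroni([1.0, 2, 3, 4], ["a", "a", "b", "b"])


class TestFisher:
    def test_progression_table_value(self):
        """9 progressors/25 nonprogressors (lympho-myeloid) vs 5/50 (other
        pathotypes): the two-sided minimum-likelihood Fisher p is 0.0379
        (cross-checked against the hypergeometric enumeration oracle below);
        the sample odds ratio is (9*50)/(25*5) = 3.6."""
        res = fisher_exact_2x2([[9, 25], [5, 50]])
        assert res.p_value == pytest.approx(0.0379, abs=5e-5)
        assert res.statistic == pytest.approx(3.6)

    def test_identical_rows_independent(self):
        res = fisher_exact_2x2([[7, 3], [7, 3]])
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(1.0)

    def test_diagonal_unit_table_enumeration(self):
        # conditional distribution has only 2 tables, each probability 1/2
        res = fisher_exact_2x2([[1, 0], [0, 1]])
        assert res.p_value == pytest.approx(1.0)

    def _enumeration_oracle(self, a, b, c, d):
        """Brute-force: sum hypergeometric probabilities <= observed."""
        n, row1, col1 = a + b + c + d, a + b, a + c
        rv = stats.hypergeom(n, row1, col1)
        lo, hi = max(0, col1 - (c + d)), min(row1, col1)
        p_obs = rv.pmf(a)
        return sum(rv.pmf(k) for k in range(lo, hi + 1) if rv.pmf(k) <= p_obs * (1 + 1e-9))

    def test_matches_enumeration_small_tables(self):
        for a, b, c, d in [(9, 25, 5, 50), (2, 3, 4, 1), (0, 5, 5, 0), (3, 0, 0, 3), (1, 1, 1, 1)]:
            res = fisher_exact_2x2([[a, b], [c, d]])
            assert res.p_value == pytest.approx(self._enumeration_oracle(a, b, c, d), abs=1e-10)

    def test_doubling_convention_flag(self):
        res = fisher_exact_2x2([[9, 25], [5, 50]], two_sided="doubling")
        a, rv = 9, stats.hypergeom(89, 34, 14)
        assert res.p_value == pytest.approx(min(1, 2 * min(rv.cdf(a), rv.sf(a - 1))), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])


class TestPairedChange:
    def test_no_change(self):
        pre = np.array([1.0, 2, 3, 4])
        res = paired_change_test(pre, pre)
        assert res.estimate == 0.0 and res.p_value == 1.0

    def test_exact_unit_shift(self):
        pre = np.array([1.0, 2, 3, 4])
        res = paired_change_test(pre, pre + 1)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_paired_t_equivalence(self, rng):
        pre = rng.normal(size=20)
        post = pre + 0.4 + rng.normal(scale=0.5, size=20)
        res = paired_change_test(pre, post)
        ref = stats.ttest_rel(post, pre)
        assert res.estimate == pytest.approx(float(np.mean(post - pre)), abs=1e-12)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_reml_random_intercept_matches_closed_form(self, rng):
        """The iterative mixed-model fit (patient random intercept, time
        fixed effect) reproduces the mean paired difference on balanced
        complete pairs."""
        pre = rng.normal(size=15)
        post = pre + 0.8 + rng.normal(scale=0.6, size=15)
        closed = paired_change_test(pre, post)
        reml = paired_change_test(pre, post, method="mixedlm")
        assert reml.estimate == pytest.approx(closed.estimate, abs=1e-6)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_change_test([1.0, 2], [2.0, 3])


class TestWard:
    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3], [9, 9, 9]], index=list("abc"))
        out = ward_cluster(mat)
        assert out["row_linkage"][0, 2] == pytest.approx(0.0)

    def test_collinear_points_first_merge(self):
        # Lance-Williams/Ward: nearest pair (0) and (1) merges first
        mat = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], index=list("abc"))
        out = ward_cluster(mat)
        first = set(out["row_linkage"][0, :2].astype(int))
        assert first == {0, 1}
        # merge height equals the Euclidean distance for singleton merges
        assert out["row_linkage"][0, 2] == pytest.approx(1.0)

    def test_leaf_order_is_permutation_and_scipy_consistent(self, rng):
        mat = pd.DataFrame(rng.normal(size=(8, 5)), index=[f"r{i}" for i in range(8)])
        out = ward_cluster(mat)
        assert sorted(out["row_order"]) == sorted(mat.index)
        ref = hierarchy.linkage(mat.to_numpy(), method="ward")
        np.testing.assert_allclose(out["row_linkage"], ref)
        assert out["row_newick"].endswith(";") and "r0" in out["row_newick"]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(pd.DataFrame([[1.0, np.nan], [2.0, 3.0]]))


class TestEular:
    @pytest.mark.parametrize(
        "base, follow, expected",
        [
            (5.6, 3.0, "good"),
            (5.6, 5.5, "none"),  # improvement 0.1 <= 0.6
            (4.4, 3.2, "moderate"),  # improvement exactly 1.2: strict >1.2 for good
            (6.5, 5.4, "none"),  # improvement 1.1 <= 1.2 with follow-up above 5.1
            (3.0, 1.0, "good"),
            (7.0, 5.0, "moderate"),  # improvement 2.0 but follow-up > 3.2
        ],
    )
    def test_bands(self, base, follow, expected):
        assert eular_response(base, follow) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            eular_response(10.5, 3.0)
        with pytest.raises(ValueError):
            eular_response(5.0, -0.1)


def test_family_adjustment_joint_bh():
    results = [
        spearman_adjusted(np.arange(10.0), np.arange(10.0) + np.random.default_rng(i).normal(size=10))
        for i in range(4)
    ]
    adjust_family(results)
    from synopath.expression import benjamini_hochberg

    expected = benjamini_hochberg([r.p_value for r in results])
    for r, e in zip(results, expected):
        assert r.adj_p == pytest.approx(e)
        assert r.adj_p >= r.p_value - 1e-12
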