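"""Clinical association statistics for the pathotype-stratified cohort.

Covers the statistical toolkit of the clinical analysis: Spearman
correlations with optional adjustment for biopsy joint category (partial
rank correlation), one-way ANOVA with Bonferroni post hoc pairwise tests,
Fisher's exact test for 2x2 tables, paired pre/post eigengene change via a
mixed model with patient random intercept, Euclidean/Ward hierarchical
clustering, EULAR treatment-response bands, and joint BH adjustment of a
declared family of p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .expression import benjamini_hochberg

__all__ = [
    "AssocResult",
    "spearman_adjusted",
    "anova_bonferroni",
    "fisher_exact_2x2",
    "paired_change_test",
    "ward_cluster",
    "eular_response",
    "adjust_family",
]


@dataclass
class AssocResult:
    """One association test: label, statistic, p, optional family-adjusted p."""

    label: str
    statistic: float
    p_value: float
    n_used: int
    estimate: float | None = None
    adj_p: float | None = None

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def adjust_family(results: list[AssocResult]) -> list[AssocResult]:
    """BH-adjust all p-values of a declared family jointly, in place."""
    adj = benjamini_hochberg([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    return results


def _rank_residuals(r: np.ndarray, joint: np.ndarray) -> np.ndarray:
    design = pd.get_dummies(pd.Series(joint).astype(str), drop_first=True).to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(r)), design])
    beta, *_ = np.linalg.lstsq(design, r, rcond=None)
    return r - design @ beta


def spearman_adjusted(
    x,
    y,
    joint=None,
    *,
    exact: bool = False,
    label: str = "spearman",
) -> AssocResult:
    """Spearman rank correlation, optionally adjusted for a joint category.

    Unadjusted: classical Spearman rho with a two-sided p from the t
    approximation, or from the exact permutation distribution of rho when
    ``exact=True`` (n <= 9).  Adjusted: both variables are rank-transformed,
    residualized on joint-category indicators, and the Pearson correlation
    of the residuals is tested on df = n - 2 - (categories - 1): a partial
    Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if joint is not None:
        joint = np.asarray(pd.Series(joint).astype(str))
        if joint.shape != x.shape:
            raise ValueError("joint must align with x and y")
        joint = joint[keep]
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    n_cat = 1 if joint is None else len(np.unique(joint))
    if joint is not None and n_cat > 1:
        rx_r = _rank_residuals(rx, joint)
        ry_r = _rank_residuals(ry, joint)
        if np.ptp(rx_r) == 0 or np.ptp(ry_r) == 0:
            raise ValueError("ranks fully explained by joint category")
        rho = float(np.corrcoef(rx_r, ry_r)[0, 1])
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])

    df = n - 2 - (n_cat - 1)
    if df < 1:
        raise ValueError("insufficient residual degrees of freedom")
    if exact:
        if joint is not None and n_cat > 1:
            raise ValueError("exact permutation p is only available unadjusted")
        if n > 9:
            raise ValueError("exact permutation p limited to n <= 9")
        rho_obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= rho_obs - 1e-12
            total += 1
        p = count / total
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return AssocResult(label=label, statistic=rho, p_value=min(p, 1.0), n_used=n, estimate=rho)


def anova_bonferroni(values, group) -> tuple[AssocResult, list[AssocResult]]:
    """One-way ANOVA across 3 groups plus Bonferroni-corrected pairwise t-tests."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(pd.Series(group).astype(str))
    if values.shape != group.shape:
        raise ValueError("values and group must align")
    levels = sorted(pd.unique(group))
    if len(levels) < 3:
        raise ValueError(f"need 3 groups, got {levels}")
    blocks = {g: values[group == g] for g in levels}
    for g, b in blocks.items():
        if b.size < 2:
            raise ValueError(f"group {g} has fewer than 2 observations")
    n_total = values.size
    k = len(levels)
    grand = values.mean()
    ssb = sum(b.size * (b.mean() - grand) ** 2 for b in blocks.values())
    ssw = sum(((b - b.mean()) ** 2).sum() for b in blocks.values())
    dfb, dfw = k - 1, n_total - k
    if ssb <= 0:
        f_stat, p = 0.0, 1.0
    elif ssw <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f_stat, dfb, dfw))
    overall = AssocResult(label="anova", statistic=float(f_stat), p_value=p, n_used=n_total)

    n_pairs = k * (k - 1) // 2
    pairwise = []
    for i, g1 in enumerate(levels):
        for g2 in levels[i + 1 :]:
            b1, b2 = blocks[g1], blocks[g2]
            if np.ptp(np.concatenate([b1, b2])) == 0:
                t, p_pair = 0.0, 1.0
            else:
                t, p_pair = stats.ttest_ind(b1, b2, equal_var=True)
            pairwise.append(
                AssocResult(
                    label=f"{g1}_vs_{g2}",
                    statistic=float(t),
                    p_value=min(1.0, float(p_pair) * n_pairs),
                    n_used=b1.size + b2.size,
                )
            )
    return overall, pairwise


def fisher_exact_2x2(table, *, odds_ratio: str = "sample", two_sided: str = "min_likelihood") -> AssocResult:
    """Fisher's exact test for a 2x2 table of nonnegative integer counts.

    Two-sided p by the minimum-likelihood convention (sum of hypergeometric
    probabilities not exceeding the observed table's), the dominant
    convention; ``two_sided="doubling"`` doubles the smaller tail instead.
    Odds ratio: unconditional sample estimate ad/bc by default,
    ``odds_ratio="conditional"`` for the conditional MLE.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = np.round(t).astype(int)
    if np.any(t < 0):
        raise ValueError("table entries must be nonnegative")
    n = int(t.sum())
    if n < 1:
        raise ValueError("table grand total must be >= 1")
    a, b, c, d = t.ravel()
    if two_sided == "min_likelihood":
        _, p = stats.fisher_exact(t, alternative="two-sided")
    elif two_sided == "doubling":
        m, nn, k = a + b, c + d, a + c
        rv = stats.hypergeom(n, m, k)
        p = min(1.0, 2.0 * min(rv.cdf(a), rv.sf(a - 1)))
    else:
        raise ValueError(f"unknown two-sided convention {two_sided!r}")
    if odds_ratio == "sample":
        orr = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    elif odds_ratio == "conditional":
        orr = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    else:
        raise ValueError(f"unknown odds ratio kind {odds_ratio!r}")
    return AssocResult(label="fisher_2x2", statistic=float(orr), p_value=float(min(p, 1.0)), n_used=n, estimate=float(orr))


def paired_change_test(score_pre, score_post, patient_id=None, *, method: str = "auto") -> AssocResult:
    """Pre/post change with patient as a random effect.

    On the balanced complete-pair design given here, the REML estimate of
    the time fixed effect equals the mean paired difference and its test is
    the paired t-test; the closed form is used by default.
    ``method="mixedlm"`` fits the random-intercept model iteratively via
    statsmodels (Wald z p-value) for cross-checking.
    """
    pre = np.asarray(score_pre, dtype=float)
    post = np.asarray(score_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("score_pre and score_post must be 1-d arrays of equal length")
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = post - pre
    estimate = float(diff.mean())
    if method == "mixedlm":
        import statsmodels.api as sm

        pid = np.arange(n) if patient_id is None else np.asarray(patient_id)[keep]
        long = pd.DataFrame(
            {
                "score": np.concatenate([pre, post]),
                "time": np.repeat([0.0, 1.0], n),
                "patient": np.tile(pid, 2),
            }
        )
        fit = sm.MixedLM.from_formula("score ~ time", groups="patient", data=long).fit(reml=True)
        return AssocResult(
            label="paired_change",
            statistic=float(fit.tvalues["time"]),
            p_value=float(fit.pvalues["time"]),
            n_used=n,
            estimate=float(fit.params["time"]),
        )
    sd = diff.std(ddof=1)
    if sd == 0:
        t = 0.0 if estimate == 0 else np.inf * np.sign(estimate)
        p = 1.0 if estimate == 0 else 0.0
    else:
        t = estimate / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return AssocResult(label="paired_change", statistic=float(t), p_value=p, n_used=n, estimate=estimate)


def ward_cluster(mat: pd.DataFrame) -> dict:
    """Row and column dendrograms (Euclidean distance, Ward's linkage).

    Returns linkage matrices (merge heights in Lance-Williams/Ward terms),
    leaf orders, and Newick renderings of both trees.
    """
    values = mat.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    if min(values.shape) < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_link = hierarchy.linkage(values, method="ward", metric="euclidean")
    col_link = hierarchy.linkage(values.T, method="ward", metric="euclidean")
    row_order = [mat.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [mat.columns[i] for i in hierarchy.leaves_list(col_link)]
    return {
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_order": row_order,
        "col_order": col_order,
        "row_newick": linkage_to_newick(row_link, [str(i) for i in mat.index]),
        "col_newick": linkage_to_newick(col_link, [str(c) for c in mat.columns]),
    }


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def eular_response(das28_baseline: float, das28_followup: float) -> str:
    """Standard EULAR response bands from baseline and follow-up DAS28.

    good: follow-up <= 3.2 and improvement > 1.2; none: improvement <= 0.6,
    or improvement <= 1.2 with follow-up > 5.1; moderate otherwise.
    """
    for name, v in (("das28_baseline", das28_baseline), ("das28_followup", das28_followup)):
        if not np.isfinite(v) or not 0.0 <= v <= 10.0:
            raise ValueError(f"{name}={v} outside [0, 10]")
    eps = 1e-9  # guard float artifacts at the published band edges
    improvement = das28_baseline - das28_followup
    if das28_followup <= 3.2 + eps and improvement > 1.2 + eps:
        return "good"
    if improvement <= 0.6 + eps or (improvement <= 1.2 + eps and das28_followup > 5.1 + eps):
        return "none"
    return "moderate"
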