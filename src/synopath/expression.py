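"""Expression-matrix handling and differential-expression statistics.

The expression container is a plain :class:`pandas.DataFrame` with genes in
rows and samples in columns, holding log2 expression values (NanoString-style
targeted panel).  :func:`read_expression` / :func:`write_expression` round-trip
the on-disk CSV layout (first column ``gene_id``).

Differential expression uses an empirical-Bayes moderated t-statistic:
per-gene residual variances are shrunk toward a common prior variance, with
the prior degrees of freedom and prior variance estimated by method of
moments on the scaled-inverse-chi-square model for gene variances.  A plain
(unmoderated) two-sample t-test is provided both as an analysis pathway of
its own and as an oracle mode for the moderated statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "read_expression",
    "write_expression",
    "validate_expression",
    "zscore_per_gene",
    "benjamini_hochberg",
    "moderated_ttest",
    "two_sample_ttest",
]


def validate_expression(mat: pd.DataFrame) -> pd.DataFrame:
    """Check the genes x samples invariants; return the validated frame."""
    if not isinstance(mat, pd.DataFrame):
        raise TypeError("expression matrix must be a pandas DataFrame (genes x samples)")
    if mat.index.duplicated().any():
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes}")
    if mat.columns.duplicated().any():
        dupes = mat.columns[mat.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes}")
    values = mat.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = mat.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ValueError(f"missing or non-finite expression values in genes: {bad}")
    return mat


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression CSV (first column gene_id)."""
    mat = pd.read_csv(path, index_col=0)
    mat.index = mat.index.astype(str)
    return validate_expression(mat)


def write_expression(mat: pd.DataFrame, path) -> None:
    validate_expression(mat)
    out = mat.copy()
    out.index.name = "gene_id"
    out.to_csv(path)


def zscore_per_gene(mat: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, SD 1 across samples.

    ``ddof=1`` (sample SD) is the default; ``ddof=0`` gives population SD.
    Zero-variance genes are an error because they cannot be standardized.
    """
    validate_expression(mat)
    values = mat.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=ddof)
    if np.any(sd == 0):
        offenders = mat.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes cannot be z-scored: {offenders}")
    centred = values - values.mean(axis=1, keepdims=True)
    return pd.DataFrame(centred / sd[:, None], index=mat.index, columns=mat.columns)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= rank(i)} min(1, m * p_(j) / j); monotone and stable
    under ties.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _split_groups(mat: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray, str, str]:
    groups = pd.Series(groups)
    if groups.index.equals(pd.RangeIndex(len(groups))):
        if len(groups) != mat.shape[1]:
            raise ValueError("groups length does not match number of samples")
        groups.index = mat.columns
    levels = pd.unique(groups.loc[mat.columns])
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {list(levels)}")
    g1, g2 = str(levels[0]), str(levels[1])
    mask1 = (groups.loc[mat.columns] == levels[0]).to_numpy()
    x1 = mat.to_numpy(dtype=float)[:, mask1]
    x2 = mat.to_numpy(dtype=float)[:, ~mask1]
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group must contain at least 2 samples")
    return x1, x2, g1, g2


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df, prior_var) for gene variances.

    Under the scaled-inverse-chi-square model, log(s2) follows a shifted
    log-F distribution; matching the mean and variance of
    e = log(s2) - digamma(df/2) + log(df/2) yields the prior degrees of
    freedom d0 (via the trigamma inverse) and the prior variance s0^2.
    Returns ``(inf, exp(mean(e)))`` when the observed spread of log
    variances is no larger than expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("gene variances must be positive to fit the prior")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if s2.size < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma; monotone decreasing so this converges fast.
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-12 * y:
            break
    return y


def _de_frame(genes, log_fc, t_stat, p, adj_p, comparison) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": np.asarray(genes, dtype=object),
            "log_fc": log_fc,
            "t_stat": t_stat,
            "p_value": p,
            "adj_p": adj_p,
            "comparison": comparison,
        }
    )


def moderated_ttest(
    mat: pd.DataFrame,
    groups,
    *,
    prior_df: float | None = None,
    prior_var: float | None = None,
    epsilon_variance: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per gene.

    Gene-wise pooled variances ``s_g^2`` (residual df ``d``) are shrunk to
    ``s_post^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)`` with the prior
    ``(d0, s0^2)`` estimated by :func:`fit_variance_prior` (override either
    via ``prior_df`` / ``prior_var``; ``prior_df=0`` reduces exactly to the
    plain pooled t).  Two-sided p-values come from the t distribution with
    posterior df ``d + d0``.  log_fc is group1 minus group2 in the order the
    levels first appear.
    """
    validate_expression(mat)
    x1, x2, g1, g2 = _split_groups(mat, groups)
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    if np.any(s2 <= 0):
        if epsilon_variance is None:
            offenders = mat.index[s2 <= 0].tolist()
            raise ValueError(
                f"zero within-group variance for genes {offenders}; "
                "pass epsilon_variance to regularize"
            )
        s2 = np.maximum(s2, epsilon_variance)

    if prior_df is None or prior_var is None:
        d0_hat, s0_hat = fit_variance_prior(s2, df)
        d0 = d0_hat if prior_df is None else prior_df
        s0_sq = s0_hat if prior_var is None else prior_var
    else:
        d0, s0_sq = prior_df, prior_var

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_post = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_post = df + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    log_fc = m1 - m2
    t = log_fc / se
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    adj = benjamini_hochberg(p)
    return _de_frame(mat.index, log_fc, t, p, adj, f"{g1}_vs_{g2}")


def two_sample_ttest(
    mat: pd.DataFrame,
    groups,
    *,
    welch: bool = False,
    epsilon_variance: float | None = None,
) -> pd.DataFrame:
    """Plain two-sample t-test per gene (pooled variance by default).

    This pathway is deliberately left unadjusted for multiple testing
    (``adj_p`` equals ``p_value``): it feeds the progressor gene screen
    where the nominal p < 0.05 count is the quantity of interest.
    """
    validate_expression(mat)
    x1, x2, g1, g2 = _split_groups(mat, groups)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    log_fc = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        se = np.sqrt(se2)
    else:
        s2 = (v1 * (n1 - 1) + v2 * (n2 - 1)) / (n1 + n2 - 2)
        if np.any(s2 <= 0):
            if epsilon_variance is None:
                offenders = mat.index[s2 <= 0].tolist()
                raise ValueError(
                    f"zero pooled variance for genes {offenders}; "
                    "pass epsilon_variance to regularize"
                )
            s2 = np.maximum(s2, epsilon_variance)
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where((se == 0) & (log_fc == 0), 1.0, p)
    return _de_frame(mat.index, log_fc, t, p, p.copy(), f"{g1}_vs_{g2}")
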