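"""Radiographic-progression prediction.

Two complementary modelling routes over a boolean 12-month progression
outcome (change in radiographic damage score >= 1):

* backward stepwise logistic regression over baseline clinical covariates
  (AIC criterion by default), via statsmodels;
* L1-penalized (lasso) logistic regression over a gene screen plus clinical
  covariates, fitted by glmnet-style IRLS + cyclic coordinate descent with
  per-variable penalty factors (so clinical covariates can be exempted from
  the penalty), with the penalty weight chosen by stratified k-fold
  cross-validation minimizing mean binomial deviance.

Discrimination is the ROC AUC (Mann-Whitney identity, ties counted 1/2),
internally validated by the bootstrap optimism correction: the *entire*
modelling recipe, including any variable screening, is refit on every
resample and the mean excess of in-resample over original-data AUC is
subtracted from the apparent AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PredictionModel",
    "SeparationError",
    "roc_auc",
    "backward_stepwise_logistic",
    "fit_l1_logistic",
    "lasso_path",
    "lasso_logistic_cv",
    "optimism_corrected_auc",
    "screen_top_k_recipe",
    "screen_lasso_recipe",
]


class SeparationError(RuntimeError):
    """Raised when logistic coefficients diverge (perfect separation)."""


@dataclass
class PredictionModel:
    selected: list[str]
    coefficients: dict[str, float]  # on the standardized scale, plus "intercept"
    lambda_: float
    apparent_auc: float | None = None
    corrected_auc: float | None = None
    n_boot: int = 0
    extra: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor for new data (columns standardized as in fit)."""
        means = self.extra.get("feature_means")
        sds = self.extra.get("feature_sds")
        eta = np.full(len(X), self.coefficients.get("intercept", 0.0))
        for name, beta in self.coefficients.items():
            if name == "intercept" or beta == 0.0:
                continue
            x = X[name].to_numpy(dtype=float)
            if means is not None:
                x = (x - means[name]) / sds[name]
            eta = eta + beta * x
        return eta


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney identity; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d and aligned")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# backward stepwise logistic regression
# ---------------------------------------------------------------------------


def _logit_fit(X: np.ndarray, y: np.ndarray):
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = model.fit(disp=0, maxiter=200)
        except Exception:
            fit = model.fit(disp=0, method="bfgs", maxiter=500)
    separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    if separated or not np.isfinite(fit.params).all() or np.abs(fit.params).max() > 1e3:
        raise SeparationError(
            "perfect separation detected (diverging logistic coefficients); "
            "consider the penalized (lasso) mode"
        )
    return fit


def _drop_aliased(X: pd.DataFrame) -> list[str]:
    """Keep a maximal linearly independent subset of columns (first wins)."""
    kept: list[str] = []
    arr = np.column_stack([np.ones(len(X))])
    for name in X.columns:
        cand = np.column_stack([arr, X[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(arr):
            kept.append(name)
            arr = cand
    return kept


def backward_stepwise_logistic(
    data: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str,
    *,
    criterion: str = "aic",
    p_remove: float = 0.10,
) -> PredictionModel:
    """Backward stepwise selection from the full logistic model.

    Repeatedly removes the variable whose removal most improves the AIC
    (``criterion="pvalue"``: removes the least significant variable with
    Wald p above ``p_remove``) until no removal improves the criterion.
    Deterministic: ties break on variable name.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    missing = [c for c in candidates + [outcome] if c not in data.columns]
    if missing:
        raise ValueError(f"columns absent from data: {missing}")
    sub = data[candidates + [outcome]]
    if sub.isna().any().any():
        raise ValueError("missing values in candidates or outcome")
    y = sub[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary with both classes present")
    n_events = int(y.sum())
    if min(n_events, len(y) - n_events) < 10:
        warnings.warn("fewer than 10 events or non-events; selection may be unstable", stacklevel=2)

    current = _drop_aliased(sub[sorted(candidates)])
    aliased = sorted(set(candidates) - set(current))
    fit = _logit_fit(sub[current].to_numpy(dtype=float), y)
    while current:
        if criterion == "aic":
            best_name, best_fit, best_aic = None, None, fit.aic
            for name in current:
                reduced = [c for c in current if c != name]
                cand_fit = _logit_fit(sub[reduced].to_numpy(dtype=float), y) if reduced else _logit_fit(
                    np.empty((len(y), 0)), y
                )
                if cand_fit.aic < best_aic - 1e-10:
                    best_name, best_fit, best_aic = name, cand_fit, cand_fit.aic
            if best_name is None:
                break
            current = [c for c in current if c != best_name]
            fit = best_fit
        elif criterion == "pvalue":
            pvals = pd.Series(fit.pvalues[1:], index=current)
            worst = pvals.idxmax()
            if pvals[worst] <= p_remove:
                break
            current = [c for c in current if c != worst]
            fit = _logit_fit(sub[current].to_numpy(dtype=float), y)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")

    coefs = {"intercept": float(fit.params[0])}
    coefs.update({name: float(b) for name, b in zip(current, fit.params[1:])})
    eta = fit.params[0] + (sub[current].to_numpy(dtype=float) @ fit.params[1:] if current else 0.0)
    model = PredictionModel(
        selected=current,
        coefficients=coefs,
        lambda_=0.0,
        apparent_auc=roc_auc(eta, y) if current else 0.5,
        extra={"aic": float(fit.aic), "deviance": float(-2 * fit.llf), "aliased_dropped": aliased},
    )
    return model


# ---------------------------------------------------------------------------
# L1-penalized logistic regression (coordinate descent)
# ---------------------------------------------------------------------------

_W_FLOOR = 1e-5


def _l1_logistic_kernel(X, y, lam_pf, b, b0, tol, max_outer, max_inner):
    """Glmnet-style IRLS + cyclic coordinate descent with active-set sweeps.

    Minimizes (1/n) * negative binomial log-likelihood + sum_j lam_pf[j]*|b_j|
    in place; returns (b, b0).  Numerically identical whether run through the
    numba-compiled or the pure-Python path.
    """
    n, p = X.shape
    for _outer in range(max_outer):
        eta = b0 + X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        for i in range(n):
            if w[i] < _W_FLOOR:
                w[i] = _W_FLOOR
        z_resid = (y - mu) / w  # working response minus current fit
        r = z_resid.copy()
        denom = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            denom[j] = s / n
        wsum = w.sum()
        b_out = b.copy()
        b0_out = b0
        sweep_all = True
        for _inner in range(max_inner):
            max_delta = 0.0
            for j in range(p):
                if not sweep_all and b[j] == 0.0:
                    continue
                if denom[j] <= 0.0:
                    continue
                rho = 0.0
                for i in range(n):
                    rho += w[i] * X[i, j] * r[i]
                rho = rho / n + denom[j] * b[j]
                g = lam_pf[j]
                if rho > g:
                    bj = (rho - g) / denom[j]
                elif rho < -g:
                    bj = (rho + g) / denom[j]
                else:
                    bj = 0.0
                delta = bj - b[j]
                if delta != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * delta
                    b[j] = bj
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            s = 0.0
            for i in range(n):
                s += w[i] * r[i]
            d0 = s / wsum
            if d0 != 0.0:
                for i in range(n):
                    r[i] -= d0
                b0 += d0
                if abs(d0) > max_delta:
                    max_delta = abs(d0)
            if max_delta < tol:
                if sweep_all:
                    break
                sweep_all = True
            else:
                sweep_all = False
        moved = abs(b0 - b0_out)
        for j in range(p):
            if abs(b[j] - b_out[j]) > moved:
                moved = abs(b[j] - b_out[j])
        if moved < tol:
            break
    return b, b0


try:  # compiled kernel when numba is available; identical pure-Python otherwise
    from numba import njit

    _l1_logistic_kernel_fast = njit(cache=True)(_l1_logistic_kernel)
except ImportError:  # pragma: no cover
    _l1_logistic_kernel_fast = _l1_logistic_kernel


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalty_factor: np.ndarray | None = None,
    *,
    coef: np.ndarray | None = None,
    intercept: float | None = None,
    tol: float = 1e-7,
    max_outer: int = 100,
    max_inner: int = 1000,
) -> tuple[np.ndarray, float]:
    """Minimize (1/n) binomial deviance/2 + lam * sum_j pf_j |b_j|.

    Glmnet-style outer IRLS loop with an inner cyclic coordinate-descent
    solve of the penalized weighted least squares problem, active-set
    iteration after the first full sweep.  The intercept is never penalized
    and initializes at the outcome log-odds (so the largest path lambda
    yields the exact null model).  X is used as given — standardize
    beforehand for scale-free penalties.  Converges when the largest
    coefficient update falls below ``tol``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, dtype=float)
    if pf.shape != (p,) or np.any(pf < 0):
        raise ValueError("penalty_factor must be nonnegative, one per column")
    b = np.zeros(p) if coef is None else coef.astype(float).copy()
    if intercept is None:
        ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
        b0 = float(np.log(ybar / (1 - ybar)))
    else:
        b0 = float(intercept)
    b, b0 = _l1_logistic_kernel_fast(X, y, lam * pf, b, b0, tol, max_outer, max_inner)
    return b, float(b0)


def binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance -2/n * log-likelihood at linear predictor eta."""
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    penalty_factor: np.ndarray,
    *,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> np.ndarray:
    """Descending lambda sequence from the smallest lambda zeroing all
    penalized coefficients (null-model gradient bound) down by
    ``lambda_min_ratio``."""
    pf = np.asarray(penalty_factor, dtype=float)
    ybar = y.mean()
    grad = np.abs(X.T @ (y - ybar)) / len(y)
    with np.errstate(divide="ignore"):
        bounds = np.where(pf > 0, grad / np.where(pf > 0, pf, 1.0), 0.0)
    lam_max = float(bounds.max())
    if lam_max <= 0:
        lam_max = 1.0
    return lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)


def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, pd.Series, pd.Series]:
    means = X.mean()
    sds = X.std(ddof=0)
    if (sds == 0).any():
        offenders = sds.index[sds == 0].tolist()
        raise ValueError(f"constant predictor columns: {offenders}")
    Z = (X - means) / sds
    return Z.to_numpy(dtype=float), means, sds


def lasso_logistic_cv(
    data: pd.DataFrame,
    candidate_genes: Sequence[str],
    candidate_clinical: Sequence[str],
    outcome: str,
    *,
    n_folds: int = 10,
    seed: int = 0,
    penalize_clinical: bool = True,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    tol: float = 1e-7,
) -> PredictionModel:
    """Cross-validated lasso logistic regression over genes + clinical covariates.

    Predictors are standardized (mean 0, SD 1); the lambda minimizing mean
    cross-validated binomial deviance over stratified folds is refit on all
    data.  With ``penalize_clinical=False`` the clinical covariates carry a
    zero penalty factor and always stay in the model.
    """
    genes = list(candidate_genes)
    clinical = list(candidate_clinical)
    if not genes and not clinical:
        raise ValueError("no candidate predictors")
    overlap = set(genes) & set(clinical)
    if overlap:
        raise ValueError(f"gene and clinical candidate names overlap: {sorted(overlap)}")
    features = genes + clinical
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary with both classes present")
    X_df = data[features].astype(float)
    if X_df.isna().any().any():
        raise ValueError("missing values among predictors")
    Z, means, sds = _standardize(X_df)
    pf = np.ones(len(features))
    if not penalize_clinical:
        pf[len(genes) :] = 0.0

    lambdas = lasso_path(Z, y, pf, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    n_folds_eff = min(n_folds, int(y.sum()), int((1 - y).sum()))
    if n_folds_eff < 2:
        raise ValueError("too few events to stratify cross-validation folds")
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    cv_dev = np.zeros(len(lambdas))
    for train_idx, test_idx in skf.split(Z, y):
        b = np.zeros(Z.shape[1])
        b0 = None
        ytr = y[train_idx]
        dev_null = binomial_deviance(ytr, np.full(len(ytr), np.log(ytr.mean() / (1 - ytr.mean()))))
        for i, lam in enumerate(lambdas):
            b, b0 = fit_l1_logistic(Z[train_idx], y[train_idx], lam, pf, coef=b, intercept=b0, tol=tol)
            eta = b0 + Z[test_idx] @ b
            cv_dev[i] += binomial_deviance(y[test_idx], eta) * len(test_idx)
            # glmnet-style path truncation: once the training fit is nearly
            # saturated, smaller lambdas only overfit further — carry the
            # boundary fit forward for the remaining path
            if binomial_deviance(ytr, b0 + Z[train_idx] @ b) < 0.01 * dev_null:
                for k in range(i + 1, len(lambdas)):
                    cv_dev[k] += binomial_deviance(y[test_idx], eta) * len(test_idx)
                break
    cv_dev /= len(y)
    best = int(np.argmin(cv_dev))
    lam_best = float(lambdas[best])

    # warm-started refit on all data down the path to the selected lambda
    b = np.zeros(Z.shape[1])
    b0 = None
    dev_null = binomial_deviance(y, np.full(len(y), np.log(y.mean() / (1 - y.mean()))))
    for lam in lambdas[: best + 1]:
        b, b0 = fit_l1_logistic(Z, y, lam, pf, coef=b, intercept=b0, tol=tol)
        if binomial_deviance(y, b0 + Z @ b) < 0.01 * dev_null:
            break
    coefs = {"intercept": float(b0)}
    coefs.update({name: float(v) for name, v in zip(features, b)})
    selected = [name for name, v in zip(features, b) if v != 0.0]
    eta = b0 + Z @ b
    return PredictionModel(
        selected=selected,
        coefficients=coefs,
        lambda_=lam_best,
        apparent_auc=roc_auc(eta, y) if len(selected) > 0 else 0.5,
        extra={
            "feature_means": means.to_dict(),
            "feature_sds": sds.to_dict(),
            "cv_deviance": cv_dev.tolist(),
            "lambda_path": lambdas.tolist(),
            "n_folds": n_folds_eff,
        },
    )


# ---------------------------------------------------------------------------
# bootstrap optimism correction
# ---------------------------------------------------------------------------


def _stratified_resample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = np.arange(len(y))
    pos, neg = idx[y.astype(bool)], idx[~y.astype(bool)]
    return np.concatenate([rng.choice(pos, size=len(pos), replace=True), rng.choice(neg, size=len(neg), replace=True)])


def optimism_corrected_auc(
    data: pd.DataFrame,
    outcome: str,
    fit_procedure: Callable[[pd.DataFrame, str, int], PredictionModel],
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Harrell-style bootstrap optimism correction of the apparent AUC.

    ``fit_procedure(data, outcome, seed) -> PredictionModel`` must contain
    the entire modelling recipe, variable screening included; it is re-run
    on every bootstrap resample (drawn with replacement, stratified by
    outcome so both classes persist).  optimism = mean over resamples of
    (AUC on the resample - AUC of the resample model on the original data);
    corrected = apparent - optimism.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary with both classes present")
    seeds = np.random.SeedSequence(seed).generate_state(n_boot + 1) % (2**31 - 1)
    model = fit_procedure(data, outcome, int(seeds[0]))
    apparent = roc_auc(model.predict(data), y)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    optimisms = []
    for i in range(n_boot):
        boot_idx = _stratified_resample(y, rng)
        boot = data.iloc[boot_idx].reset_index(drop=True)
        boot_model = fit_procedure(boot, outcome, int(seeds[i + 1]))
        auc_boot = roc_auc(boot_model.predict(boot), y[boot_idx])
        auc_test = roc_auc(boot_model.predict(data), y)
        optimisms.append(auc_boot - auc_test)
    optimism = float(np.mean(optimisms))
    return {
        "apparent_auc": float(apparent),
        "optimism": optimism,
        "corrected_auc": float(apparent - optimism),
        "n_boot": n_boot,
        "model": model,
    }


# ---------------------------------------------------------------------------
# packaged modelling recipes (refit wholesale inside the bootstrap)
# ---------------------------------------------------------------------------


def screen_logistic_recipe(
    gene_cols: Sequence[str],
    *,
    alpha_screen: float = 0.05,
    k_min: int = 2,
    k_max: int = 8,
) -> Callable:
    """Recipe: unadjusted two-sample-t gene screen at ``alpha_screen``
    (progressors vs nonprogressors), floored at ``k_min`` genes so the model
    is never degenerate and capped at ``k_max`` (smallest p first), then an
    unpenalized logistic fit on the survivors."""

    gene_cols = list(gene_cols)

    def fit(data: pd.DataFrame, outcome: str, seed: int) -> PredictionModel:
        y = data[outcome].to_numpy(dtype=float)
        X = data[gene_cols].to_numpy(dtype=float)
        pos, neg = X[y == 1], X[y == 0]
        n1, n0 = len(pos), len(neg)
        s2 = (pos.var(axis=0, ddof=1) * (n1 - 1) + neg.var(axis=0, ddof=1) * (n0 - 1)) / (n1 + n0 - 2)
        se = np.sqrt(np.clip(s2, 1e-12, None) * (1 / n1 + 1 / n0))
        t = (pos.mean(axis=0) - neg.mean(axis=0)) / se
        p = 2.0 * stats.t.sf(np.abs(t), n1 + n0 - 2)
        idx = np.flatnonzero(p < alpha_screen)
        if len(idx) > k_max:
            idx = idx[np.argsort(p[idx], kind="mergesort")][:k_max]
        if len(idx) < k_min:
            idx = np.argsort(p, kind="mergesort")[:k_min]
        chosen = [gene_cols[i] for i in idx]
        Z, means, sds = _standardize(data[chosen].astype(float))
        b, b0 = fit_l1_logistic(Z, y, 0.0, np.ones(len(chosen)), tol=1e-7)
        coefs = {"intercept": float(b0)} | {c: float(v) for c, v in zip(chosen, b)}
        return PredictionModel(
            selected=chosen,
            coefficients=coefs,
            lambda_=0.0,
            extra={"feature_means": means.to_dict(), "feature_sds": sds.to_dict()},
        )

    return fit


def screen_top_k_recipe(gene_cols: Sequence[str], k: int = 8) -> Callable:
    """Recipe: keep the k genes most associated with outcome (two-sample t),
    fit an unpenalized logistic model on them.  Deliberately aggressive
    selection for demonstrating optimism."""

    gene_cols = list(gene_cols)

    def fit(data: pd.DataFrame, outcome: str, seed: int) -> PredictionModel:
        y = data[outcome].to_numpy(dtype=float)
        X = data[gene_cols].to_numpy(dtype=float)
        pos, neg = X[y == 1], X[y == 0]
        n1, n0 = len(pos), len(neg)
        s2 = (pos.var(axis=0, ddof=1) * (n1 - 1) + neg.var(axis=0, ddof=1) * (n0 - 1)) / (n1 + n0 - 2)
        se = np.sqrt(np.clip(s2, 1e-12, None) * (1 / n1 + 1 / n0))
        t = np.abs(pos.mean(axis=0) - neg.mean(axis=0)) / se
        order = np.argsort(-t, kind="mergesort")[:k]
        chosen = [gene_cols[i] for i in order]
        Z, means, sds = _standardize(data[chosen].astype(float))
        b, b0 = fit_l1_logistic(Z, y, 0.0, np.ones(len(chosen)), tol=1e-8)
        coefs = {"intercept": float(b0)} | {c: float(v) for c, v in zip(chosen, b)}
        return PredictionModel(
            selected=chosen,
            coefficients=coefs,
            lambda_=0.0,
            extra={"feature_means": means.to_dict(), "feature_sds": sds.to_dict()},
        )

    return fit


def screen_lasso_recipe(
    gene_cols: Sequence[str],
    clinical_cols: Sequence[str],
    *,
    alpha_screen: float = 0.05,
    n_folds: int = 10,
    penalize_clinical: bool = True,
    n_lambda: int = 100,
) -> Callable:
    """Full published-style recipe: screen genes by unadjusted two-sample t
    (p < alpha_screen) between progressors and nonprogressors, then lasso
    over screened genes + clinical covariates with CV-selected lambda."""

    gene_cols = list(gene_cols)
    clinical_cols = list(clinical_cols)

    def fit(data: pd.DataFrame, outcome: str, seed: int) -> PredictionModel:
        y = data[outcome].to_numpy(dtype=float)
        X = data[gene_cols].to_numpy(dtype=float)
        pos, neg = X[y == 1], X[y == 0]
        n1, n0 = len(pos), len(neg)
        s2 = (pos.var(axis=0, ddof=1) * (n1 - 1) + neg.var(axis=0, ddof=1) * (n0 - 1)) / (n1 + n0 - 2)
        se = np.sqrt(np.clip(s2, 1e-12, None) * (1 / n1 + 1 / n0))
        t = (pos.mean(axis=0) - neg.mean(axis=0)) / se
        p = 2.0 * stats.t.sf(np.abs(t), n1 + n0 - 2)
        screened = [g for g, pv in zip(gene_cols, p) if pv < alpha_screen]
        return lasso_logistic_cv(
            data,
            screened,
            clinical_cols,
            outcome,
            n_folds=n_folds,
            seed=seed,
            penalize_clinical=penalize_clinical,
            n_lambda=n_lambda,
        )

    return fit
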