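"""Progression modelling: AUC, stepwise logistic, L1 coordinate descent,
cross-validated lasso, and bootstrap optimism correction."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synopath.progression import (
    SeparationError,
    backward_stepwise_logistic,
    binomial_deviance,
    fit_l1_logistic,
    lasso_logistic_cv,
    lasso_path,
    optimism_corrected_auc,
    roc_auc,
    screen_logistic_recipe,
)


def _logistic_data(rng, n=200, p=16, beta=None, intercept=-0.5):
    X = rng.standard_normal((n, p))
    eta = intercept + (X @ beta if beta is not None else 0.0)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    cols = [f"x{i}" for i in range(p)]
    df = pd.DataFrame(X, columns=cols)
    df["outcome"] = y
    return df, cols


class TestRocAuc:
    def test_perfect_and_constant(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5

    def test_pair_counting_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1], dtype=bool)
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_matches_brute_force_pairs_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = True
            labels[-1] = False
        pos, neg = scores[labels], scores[~labels]
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_complement_identity_tie_free(self, rng):
        scores = rng.permutation(np.linspace(0, 1, 20))
        labels = rng.random(20) < 0.5
        labels[0], labels[1] = True, False
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.5], [1, 1])


class TestStepwise:
    def test_planted_predictor_retained(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            beta = np.zeros(16)
            beta[3] = 1.5
            df, cols = _logistic_data(rng, n=200, beta=beta)
            model = backward_stepwise_logistic(df, cols, "outcome")
            hits += "x3" in model.selected
        assert hits >= 9

    def test_null_model_near_empty(self):
        """With the outcome independent of all 16 candidates the selected
        model is near-empty: under the 0.05 Wald criterion at most ~0.8
        noise covariates survive in expectation; AIC retains about
        p * P(chi2_1 > 2) ~ 2.5, so its average is bounded looser."""
        sizes_p, sizes_aic = [], []
        for seed in range(100, 106):
            rng = np.random.default_rng(seed)
            df, cols = _logistic_data(rng, n=200)
            m_p = backward_stepwise_logistic(df, cols, "outcome", criterion="pvalue", p_remove=0.05)
            m_aic = backward_stepwise_logistic(df, cols, "outcome")
            sizes_p.append(len(m_p.selected))
            sizes_aic.append(len(m_aic.selected))
        assert np.mean(sizes_p) <= 2.0
        assert np.mean(sizes_aic) <= 4.0

    def test_collinear_pair_dropped_same_deviance(self):
        rng = np.random.default_rng(1)
        beta = np.array([1.0, 0.0, 0.0])
        df, cols = _logistic_data(rng, n=150, p=3, beta=beta)
        df["x_dup"] = df["x0"]
        model = backward_stepwise_logistic(df, cols + ["x_dup"], "outcome")
        assert not ({"x0", "x_dup"} <= set(model.selected))
        ref = backward_stepwise_logistic(df, cols, "outcome")
        assert model.extra["deviance"] == pytest.approx(ref.extra["deviance"], abs=1e-6)

    def test_separation_raises(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(12), np.ones(12)], "outcome": np.r_[np.zeros(12), np.ones(12)]})
        df["z"] = np.tile([0.1, -0.2, 0.3], 8)
        with pytest.raises(SeparationError):
            backward_stepwise_logistic(df, ["x", "z"], "outcome")


class TestL1Solver:
    def test_lambda_zero_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        df, cols = _logistic_data(rng, n=150, p=5, beta=np.array([1.0, -0.7, 0.3, 0, 0]))
        Z = (df[cols] - df[cols].mean()) / df[cols].std(ddof=0)
        b, b0 = fit_l1_logistic(Z.to_numpy(), df["outcome"].to_numpy(), 0.0, np.ones(5), tol=1e-9)
        ref = sm.Logit(df["outcome"], sm.add_constant(Z)).fit(disp=0)
        np.testing.assert_allclose(np.r_[b0, b], ref.params, atol=1e-6)

    def test_lambda_infinite_gives_prevalence_intercept(self, rng):
        df, cols = _logistic_data(rng, n=100, p=4)
        y = df["outcome"].to_numpy()
        Z = ((df[cols] - df[cols].mean()) / df[cols].std(ddof=0)).to_numpy()
        b, b0 = fit_l1_logistic(Z, y, 5.0, np.ones(4))
        assert np.all(b == 0.0)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_nonzero_count_monotone_along_path(self, rng):
        df, cols = _logistic_data(rng, n=120, p=12, beta=np.r_[np.array([1.5, -1.0, 0.8]), np.zeros(9)])
        y = df["outcome"].to_numpy()
        Z = ((df[cols] - df[cols].mean()) / df[cols].std(ddof=0)).to_numpy()
        pf = np.ones(12)
        lams = lasso_path(Z, y, pf, n_lambda=30, lambda_min_ratio=1e-3)
        counts = []
        b, b0 = np.zeros(12), 0.0
        for lam in lams:
            b, b0 = fit_l1_logistic(Z, y, lam, pf, coef=b, intercept=b0)
            counts.append(int((b != 0).sum()))
        # descending lambda path: support can only grow (checked at knots)
        assert counts[0] == 0
        assert all(c2 >= c1 - 1 for c1, c2 in zip(counts, counts[1:]))

    def test_penalty_factor_zero_keeps_variable(self, rng):
        df, cols = _logistic_data(rng, n=100, p=4, beta=np.array([0.5, 0, 0, 0]))
        y = df["outcome"].to_numpy()
        Z = ((df[cols] - df[cols].mean()) / df[cols].std(ddof=0)).to_numpy()
        b, _ = fit_l1_logistic(Z, y, 1.0, np.array([1.0, 1.0, 1.0, 0.0]))
        assert np.all(b[:3] == 0.0)
        assert b[3] != 0.0  # unpenalized coordinate converges to its MLE direction


R_GLMNET = """
suppressMessages(library(glmnet))
args <- commandArgs(trailingOnly=TRUE)
d <- read.csv(args[1])
x <- as.matrix(d[, -ncol(d)])
y <- d[, ncol(d)]
lam <- as.numeric(args[2])
fit <- glmnet(x, y, family="binomial", lambda=lam, standardize=FALSE, thresh=1e-14, maxit=1e6)
co <- as.numeric(coef(fit))
write.csv(data.frame(coef=co), args[3], row.names=FALSE)
"""


def test_l1_solver_matches_glmnet(tmp_path, rng):
    """Independent oracle: coordinate-descent solution at a fixed lambda
    agrees with the reference penalized-regression implementation."""
    df, cols = _logistic_data(rng, n=120, p=8, beta=np.r_[np.array([1.2, -0.8]), np.zeros(6)])
    Z = ((df[cols] - df[cols].mean()) / df[cols].std(ddof=0)).to_numpy()
    y = df["outcome"].to_numpy()
    lam = 0.05
    b, b0 = fit_l1_logistic(Z, y, lam, np.ones(8), tol=1e-10)
    data = pd.DataFrame(Z, columns=cols)
    data["y"] = y
    csv = tmp_path / "d.csv"
    data.to_csv(csv, index=False)
    script = tmp_path / "glmnet.R"
    script.write_text(R_GLMNET)
    out = tmp_path / "coef.csv"
    subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv), str(lam), str(out)],
        check=True,
        capture_output=True,
    )
    ref = pd.read_csv(out)["coef"].to_numpy()
    np.testing.assert_allclose(np.r_[b0, b], ref, atol=2e-4)


class TestLassoCV:
    def test_planted_genes_recovered(self):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            n, p = 300, 46
            X = rng.standard_normal((n, p))
            rf = rng.standard_normal(n)
            beta = np.zeros(p)
            beta[:5] = 0.9
            eta = -1.0 + X @ beta + 0.8 * rf
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            df = pd.DataFrame(X, columns=[f"g{i}" for i in range(p)])
            df["rf_titre"] = rf
            df["outcome"] = y
            model = lasso_logistic_cv(
                df, [f"g{i}" for i in range(p)], ["rf_titre"], "outcome", n_folds=10, seed=seed
            )
            hits.append(sum(f"g{i}" in model.selected for i in range(5)))
        assert np.median(hits) >= 4

    def test_deterministic_under_seed(self, rng):
        df, cols = _logistic_data(rng, n=100, p=10, beta=np.r_[np.ones(2), np.zeros(8)])
        m1 = lasso_logistic_cv(df, cols[:6], cols[6:], "outcome", n_folds=5, seed=42)
        m2 = lasso_logistic_cv(df, cols[:6], cols[6:], "outcome", n_folds=5, seed=42)
        assert m1.lambda_ == m2.lambda_
        assert m1.coefficients == m2.coefficients

    def test_single_class_rejected(self, rng):
        df, cols = _logistic_data(rng, n=50, p=4)
        df["outcome"] = 1.0
        with pytest.raises(ValueError):
            lasso_logistic_cv(df, cols, [], "outcome")

    def test_overlapping_candidates_rejected(self, rng):
        df, cols = _logistic_data(rng, n=50, p=4)
        with pytest.raises(ValueError, match="overlap"):
            lasso_logistic_cv(df, cols, cols[:1], "outcome")

    def test_unpenalized_clinical_stays_in_model(self, rng):
        beta = np.r_[np.zeros(8), np.array([1.2])]
        df, cols = _logistic_data(rng, n=200, p=9, beta=beta)
        model = lasso_logistic_cv(
            df, cols[:8], cols[8:], "outcome", n_folds=5, seed=0, penalize_clinical=False
        )
        assert "x8" in model.selected


class TestOptimism:
    def test_separable_fixed_model_no_optimism(self):
        n = 40
        x = np.r_[np.linspace(-3, -1, n // 2), np.linspace(1, 3, n // 2)]
        df = pd.DataFrame({"x": x, "outcome": np.r_[np.zeros(n // 2), np.ones(n // 2)]})

        def fixed_recipe(data, outcome, seed):
            from synopath.progression import PredictionModel

            return PredictionModel(selected=["x"], coefficients={"intercept": 0.0, "x": 1.0}, lambda_=0.0)

        res = optimism_corrected_auc(df, "outcome", fixed_recipe, n_boot=30, seed=3)
        assert res["apparent_auc"] == 1.0
        assert res["optimism"] == pytest.approx(0.0, abs=1e-12)
        assert res["corrected_auc"] == pytest.approx(1.0)

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((60, 10))
        df = pd.DataFrame(X, columns=[f"g{i}" for i in range(10)])
        df["outcome"] = (rng.random(60) < 0.4).astype(float)
        recipe = screen_logistic_recipe([f"g{i}" for i in range(10)], k_max=3)
        r1 = optimism_corrected_auc(df, "outcome", recipe, n_boot=25, seed=11)
        r2 = optimism_corrected_auc(df, "outcome", recipe, n_boot=25, seed=11)
        assert r1["corrected_auc"] == r2["corrected_auc"]

    def test_corrected_below_apparent_with_signal(self):
        rng = np.random.default_rng(8)
        n, p = 90, 20
        X = rng.standard_normal((n, p))
        beta = np.r_[np.array([1.0, 0.8]), np.zeros(p - 2)]
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta - 0.6)))).astype(float)
        df = pd.DataFrame(X, columns=[f"g{i}" for i in range(p)])
        df["outcome"] = y
        recipe = screen_logistic_recipe([f"g{i}" for i in range(p)])
        res = optimism_corrected_auc(df, "outcome", recipe, n_boot=60, seed=5)
        assert res["corrected_auc"] <= res["apparent_auc"] + 1e-12

    def test_invalid_n_boot(self, rng):
        df, cols = _logistic_data(rng, n=40, p=3)
        with pytest.raises(ValueError):
            optimism_corrected_auc(df, "outcome", screen_logistic_recipe(cols), n_boot=0, seed=1)


def test_binomial_deviance_matches_sklearn(rng):
    from sklearn.metrics import log_loss

    y = (rng.random(50) < 0.5).astype(float)
    eta = rng.normal(size=50)
    mu = 1 / (1 + np.exp(-eta))
    assert binomial_deviance(y, eta) == pytest.approx(2 * log_loss(y, mu), rel=1e-9)
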