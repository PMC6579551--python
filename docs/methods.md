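# Methods

`synopath` implements a synovial-tissue stratification analysis for early,
treatment-naive rheumatoid arthritis: rule-based histological pathotyping,
construction of pathotype-specific gene panels from targeted (NanoString-style)
log2 expression, per-sample module *eigengene* scores, clinical association
statistics, and radiographic-progression prediction with bootstrap internal
validation. Because patient-level cohort data are not distributable, the
package carries a synthetic cohort generator whose defaults encode the study
structure; every stage is exercised and tested against it.

## Pathotype classification

Biopsies are graded 0–4 for CD20 (B cells), CD3 (T cells), CD68 in lining and
sublining (macrophages) and CD138 (plasma cells), plus a 0–3 grade for lymphoid
aggregate organisation; biopsies without an intact lining layer are
ungradeable. Rules apply in priority order:

1. **lympho-myeloid** — aggregate grade ≥ 2 with CD20 ≥ 2, *or* CD138 > 2;
2. **diffuse-myeloid** — CD68 sublining ≥ 2, CD20 ≤ 1, CD138 ≤ 2;
3. **pauci-immune-fibroid** — CD68 sublining < 2 and CD3, CD20, CD138 all < 1;
4. otherwise **ungraded**.

The published wording of these criteria is ambiguous at two points: the
grouping of the "and/or" clauses, and the CD138 cut shared between rules 1
and 2. We adopt the reading above because it makes the three rules logically
disjoint (verified by exhaustive enumeration of all 25 000 grade combinations)
and consistent with diffuse-myeloid tissue being poor in B/plasma cells; both
cut-points are exposed in `RuleConfig` so alternative readings remain testable.
Samples matching no rule fall through to ungraded rather than being
force-assigned.

## Differential expression and gene panels

Group comparisons use an empirical-Bayes moderated t: per-gene pooled
variances s²_g (residual df d) are shrunk to
s²_post = (d₀·s₀² + d·s²_g)/(d₀ + d), with the prior (d₀, s₀²) fitted by
method of moments on log variances under the scaled-inverse-chi-square model
(trigamma matching); the statistic is referred to a t distribution with
d + d₀ df. `prior_df=0` recovers the plain pooled t exactly, and the tests
cross-check the implementation against the reference linear-model
implementation (limma via Rscript) to 1e-5 on t statistics. Multiple testing
uses our Benjamini–Hochberg step-up implementation (tested against the hand
formula and statsmodels). Note the moderated t with an *estimated* prior is
deliberately not invariant to per-gene rescaling — shrinkage depends on the
cross-gene variance distribution — whereas the plain-t pathway is.

A pathotype's gene set contains genes elevated in that pathotype versus *each*
other pathotype at BH-adjusted p < 0.01 (adjustment within each pairwise
comparison, the convention of treating each contrast as one DE analysis).
Requiring a positive log-fold-change in both contrasts makes the three sets
disjoint. Panels are trimmed to the k = 50 genes with the largest |Pearson
correlation| with PC1 of the z-scored set (absolute correlation by default;
signed ranking behind a flag; ties break on gene identifier).

## Eigengene scores

The module eigengene is the first principal component (SVD) of the per-gene
z-scored module submatrix across samples, scaled by its singular value. PC1's
sign is arbitrary, so it is stabilized to correlate positively with mean
z-scored module expression. Adjustment for biopsy joint position residualizes
the score on joint-category indicators by least squares *after* PCA (the
adjustment modifies scores, not the matrix; pre-PCA residualization is
available by flag). Scores standardized to mean 0/SD 1 feed the group-mean ±
SEM tables used for radar-style summaries.

## Clinical statistics

* **Correlations** — Spearman rho; two-sided p from the t approximation, or
  the exact permutation distribution for n ≤ 9. "Adjusted for joint type" is
  implemented as a partial rank correlation: rank-transform both variables,
  residualize each on joint indicators, correlate residuals, and reduce the
  df by (categories − 1). Declared families of tests are BH-adjusted jointly.
* **Group comparisons** — one-way ANOVA with Bonferroni-corrected pairwise
  pooled t tests (multiplier 3, capped at 1). Degenerate inputs (zero
  between-group scatter) return F = 0, p = 1 rather than NaN.
* **2×2 tables** — Fisher's exact test, two-sided by the minimum-likelihood
  convention (doubling rule behind a flag); sample odds ratio ad/bc by
  default, conditional MLE by flag. Verified against exhaustive
  hypergeometric enumeration for every table with total ≤ 30.
* **Paired pre/post change** — a mixed model with patient random intercept
  and time fixed effect. On the balanced complete-pair design the REML
  solution is the mean paired difference with the paired-t test, which the
  default closed form computes exactly; an iterative `MixedLM` route is kept
  for cross-checking and unbalanced extensions.
* **Clustering** — Euclidean/Ward agglomeration (Lance–Williams update via
  scipy) on rows and columns, with leaf orders and Newick exports.
* **EULAR response** — good iff attained DAS28 ≤ 3.2 and improvement > 1.2;
  none iff improvement ≤ 0.6, or ≤ 1.2 with attained DAS28 > 5.1; moderate
  otherwise. Band comparisons carry a 1e-9 guard so decimal edge cases
  (e.g. 4.4 → 3.2) land on the intended side of the float representation.

## Progression prediction

* **Backward stepwise logistic** (statsmodels) from 16 baseline clinical
  covariates; default criterion AIC (Wald-p mode behind a flag); exactly
  aliased columns are pre-dropped (mirroring R's NA-aliasing) so collinear
  inputs behave predictably; perfect separation raises an error suggesting
  the penalized mode. Note backward-AIC retains ≈ p·P(χ²₁ > 2) ≈ 16 % of
  pure-noise covariates by construction; the near-empty-null property is a
  p-value-criterion property.
* **L1-penalized logistic regression** — our own glmnet-style solver:
  outer IRLS with inner cyclic coordinate descent, active-set sweeps,
  warm-started descending lambda path (100 values, ratio 1e-4), per-variable
  penalty factors (zero for `penalize_clinical=False`), convergence at 1e-7
  max coefficient change, and glmnet-style path truncation once the training
  deviance falls below 1 % of the null deviance. Lambda is chosen by
  stratified k-fold CV minimizing mean binomial deviance (misclassification
  behind a flag). The solver is verified against statsmodels at λ = 0 (1e-6)
  and against glmnet (Rscript) at fixed λ (2e-4). The kernel runs through
  numba when available; the pure-Python fallback is the same code path.
* **Discrimination** — ROC AUC by the Mann–Whitney identity with ties
  counted ½, validated against brute-force pair counting.
* **Internal validation** — Harrell-style bootstrap optimism correction:
  the *entire* recipe (screens and selection included) is refit on each of
  n_boot outcome-stratified resamples; optimism is the mean excess of
  in-resample AUC over original-data AUC; corrected = apparent − optimism.
  A partial-refit mode is not provided — honest validation re-runs
  everything. A practical caveat our own simulations quantify: with n ≈ 90
  and aggressive variable search the estimator retains residual optimism of
  roughly a third of (apparent − 0.5), because resample models are scored on
  an original sample they ~63 % overlap; the honesty checks therefore assert
  behaviour averaged over replicate null datasets and document the residual
  bias rather than assuming the estimator is exactly unbiased.

## Synthetic cohort generator

The generator emulates the study's data structure, not its biology. Defaults
are the study conditions: 144 recruited, gradeable fraction 129/144, class
mixing 51:44:34, a 242-gene panel (3 × 50 module genes + 92 background),
wrist-dominant biopsy joints (65 %), and ~16 % radiographic progression
(≈ 26 % in lympho-myeloid vs ≈ 9 % elsewhere).

Per patient, a latent class is drawn, then three latent module factors
(lymphoid, myeloid, fibroid) with class-dependent means in units of
`module_shift` (default 2.0 log2 units, i.e. ≈ 4-fold elevation of a module
in its own class; the lympho-myeloid class also carries a third of a shift on
the myeloid factor, since lymphoid-rich tissue is myeloid-rich too) plus
residuals correlated as lymphoid–myeloid +0.4 and fibroid −0.3 to both.
Expression is generated directly on the log2 scale: per-gene baseline
(uniform 6–12) + module factor + a small additive joint-category offset +
N(0, noise_sd²) noise, `noise_sd = 1.0`, so the default shift equals twice
the noise SD. Raw count simulation and positive-control normalization are
not modelled — the analysis operates on log2 values throughout.

IHC grades are factor-discretized ordinals clamped, with probability
`ihc_fidelity = 0.95`, into the latent class's rule region; the complement
produces rule-boundary and misclassified cases. Clinical covariates are
linear in the inflammatory factors with noise (DAS28 around 5.6, ESR/CRP,
ultrasound ST/PD, HAQ, joint counts); RF/ACPA titres are log-normal with a
lymphoid effect; serum CXCL13/MMP3 track lymphoid/myeloid and sICAM1/IL-8
only weakly, mirroring the reported contrast. Six-month DAS28 improvement
averages 1.8 (typical csDMARD response) with myeloid/lymphoid-dependent
gains; EULAR bands derive responder status, and in good responders the
inflammatory factors relax toward the population mean (fractional
`treatment_effect = 0.8`) with a fibroid rise, while nonresponders show a
muted lymphoid decrease only. Progression is Bernoulli in a logistic model
on the lymphoid factor and standardized log RF titre; ΔSHSS is 1 + Poisson
for progressors and 0 otherwise. Baseline expression covers 111/129 graded
samples and 6-month expression 68 of those, matching the study's assay
coverage. One seed drives everything through named child seed sequences, so
bundles are bit-identical per seed.

What the generator does *not* emulate: count-level measurement error,
batch/hybridization effects, missing clinical data, informative dropout, and
real gene–gene correlation beyond the three-factor structure. Passing
recovery tests therefore demonstrates the pipeline's statistical machinery
under its stated assumptions, not performance on real cohorts.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on small matrices (tens of genes/samples) with
frozen or derandomized seeds. Cohort-level checks use the full 144-patient
default; panel size is the full 242 genes for recovery checks and a reduced
60–90-gene panel where only pipeline plumbing is exercised. The
internal-validation honesty check uses n = 90 with 46 candidate genes, 200
bootstrap repetitions and 24 replicate noise datasets (the acceptance script
reports the same quantities from 8 replicates at 100 repetitions). These
sizes are the package's own choices for routine verification; all analyses
scale to larger inputs through the same interfaces.

## Known limitations

* The moderated-t prior fit assumes a common variance model across a panel of
  hundreds of genes; with very few genes the prior df estimate is unstable
  (it falls back to an infinite-prior pooled estimate when the observed
  log-variance spread is sub-Poisson).
* The partial Spearman correlation ("adjusted for joint type") is one of
  several defensible constructions; stratified rho averaging is not
  implemented, only flagged as an alternative in the interface design.
* Bootstrap optimism correction under aggressive selection at small n keeps
  a residual optimistic bias (see above); corrected AUCs from such settings
  should be read as upper bounds on honest discrimination.
* The generator's clinical-covariate model is linear-Gaussian with clipping;
  it reproduces correlation signs and magnitudes coarsely, not full marginal
  distributions.
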