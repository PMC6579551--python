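# synopath

Synovial pathotype stratification for early, treatment-naive rheumatoid
arthritis (RA): who this is for is the translational rheumatology analyst who
has semiquantitative synovial immunohistochemistry (IHC) grades, a targeted
log2 expression panel, clinical covariates and longitudinal outcomes per
patient, and wants to reproduce the full stratification workflow —

1. **Pathotyping** — priority-ordered rules over IHC grades (CD20, CD3,
   CD68 lining/sublining, CD138, aggregate organisation) assign each
   gradeable biopsy to *lympho-myeloid*, *diffuse-myeloid* or
   *pauci-immune-fibroid*.
2. **Gene panels & eigengenes** — per pathotype, genes elevated against each
   of the other two (pairwise empirical-Bayes moderated t, BH-adjusted
   p < 0.01), trimmed to the 50 genes best correlated with the set's first
   principal component; each sample is then scored with the module
   *eigengene* E = PC1 of the z-scored module expression, sign-stabilized
   and residualized on biopsy joint position.
3. **Clinical associations** — joint-adjusted partial Spearman correlations
   (BH family adjustment), ANOVA + Bonferroni group comparisons, Fisher
   exact 2×2 tests, mixed-model paired pre/post eigengene change,
   Euclidean/Ward clustering, EULAR response bands.
4. **Progression prediction** — backward stepwise logistic selection over 16
   baseline clinical covariates; an unadjusted two-sample-t gene screen
   (p < 0.05, progressors vs nonprogressors) feeding an L1-penalized
   (lasso) logistic model with λ chosen by 10-fold cross-validated binomial
   deviance; discrimination reported as apparent AUC and Harrell-style
   bootstrap **optimism-corrected AUC**, with the entire recipe (screens
   included) refit in every resample:
   `AUC_corrected = AUC_apparent − mean_b(AUC_boot,b − AUC_orig,b)`.

Patient-level cohort data are not distributable, so the package ships a
synthetic cohort generator (`synopath.simulate`) whose defaults encode the
study structure — 144 recruited, ~90 % gradeable, 51:44:34 class mixing, a
242-gene panel with three planted 50-gene lineage modules, correlated
clinical covariates and a ~16 % radiographic-progression outcome — and every
stage is tested against it. See `docs/methods.md` for the model details and
assumptions.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_classify_pathotypes.py
python analysis/03_build_signatures.py
python analysis/04_clinical_associations.py
python analysis/05_predict_progression.py --boot 200 --seed 0
```

Output (seed 0, abridged):

```
127/144 biopsies gradeable (88.2%, failure 11.8%)
  lympho_myeloid: n=47 (37%)  diffuse_myeloid: n=40 (31%)  pauci_immune_fibroid: n=40 (31%)
agreement with generator's latent class among graded: 99.2%

lymphoid: 50 genes pass pairwise DE; myeloid: 47; fibroid: 50
inter-eigengene correlations: lymphoid~myeloid +0.21, fibroid~lymphoid −0.44, fibroid~myeloid −0.67

strongest eigengene–clinical correlations (joint-adjusted): myeloid~esr 0.88,
myeloid~crp 0.85, lymphoid~rf_titre 0.83, lymphoid~acpa_titre 0.75
good responders, fibroid eigengene change: +1.47 (p=1.7e-08, n=17)

stepwise clinical model keeps 8/16 covariates; apparent AUC 0.934
lasso model: lambda=0.0393, 8 nonzero terms (2 lymphoid genes, 3 fibroid
genes, 1 background gene, ACPA titre, pathotype)
apparent AUC 0.948, optimism 0.075, corrected AUC 0.873 (200 resamples)
```

Reading this: the rule classifier recovers the generator's latent tissue
classes almost perfectly; the three planted lineage modules are re-derived
from expression alone with the expected inter-module correlation signs
(inflammatory modules positively coupled, fibroid opposed); the myeloid
eigengene tracks acute-phase disease activity while the lymphoid eigengene
tracks autoantibody titres; and the penalized gene+clinical model predicts
12-month radiographic progression with internally validated discrimination —
the optimism term is what the apparent AUC loses once selection is honestly
re-run inside each bootstrap resample.

The same stages are available as a CLI (`synopath simulate | classify |
signatures | predict | run-all`) for users bringing their own
`expression.csv` / `ihc.csv` / `clinical.csv` / `outcomes.csv`.

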