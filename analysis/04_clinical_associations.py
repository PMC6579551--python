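#!/usr/bin/env python
"""Clinical associations of the module eigengenes.

Joint-position-adjusted Spearman correlations of each eigengene with disease
activity, acute-phase, autoantibody, ultrasound and serum measures (one BH
family), pathotype group comparisons (ANOVA + Bonferroni), the
progression-by-pathotype Fisher test, and paired pre/post eigengene change
in EULAR good responders.
"""

import json
from pathlib import Path

import pandas as pd

from synopath import cohort_stats
from synopath.histopathology import Pathotype
from synopath.signatures import GeneSet, eigengene_score
from synopath.simulate import read_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"

CLINICAL_VARS = [
    "das28_esr_baseline", "esr", "crp", "rf_titre", "acpa_titre",
    "vas", "tjc", "sjc", "haq", "us_st_bj", "us_pd_bj", "us_st_max", "us_pd_max",
    "serum_cxcl13", "serum_sicam1", "serum_mmp3", "serum_il8",
]


def main():
    bundle = read_bundle(RESULTS / "cohort")
    labels = pd.read_csv(RESULTS / "pathotype_labels.csv", index_col=0).iloc[:, 0]
    scores = pd.read_csv(RESULTS / "eigengenes.csv", index_col="sample_id")
    clin = bundle.clinical.loc[scores.index]
    joint = clin["joint_category"].to_numpy()

    results = []
    for module in scores.columns:
        for var in CLINICAL_VARS:
            results.append(
                cohort_stats.spearman_adjusted(
                    scores[module].to_numpy(), clin[var].to_numpy(dtype=float), joint,
                    label=f"{module}~{var}",
                )
            )
    cohort_stats.adjust_family(results)
    table = pd.DataFrame(
        [{"pair": r.label, "rho": r.statistic, "p": r.p_value, "adj_p": r.adj_p, "n": r.n_used} for r in results]
    )
    table.to_csv(RESULTS / "eigengene_clinical_correlations.csv", index=False)
    top = table.reindex(table.rho.abs().sort_values(ascending=False).index).head(8)
    print("strongest eigengene-clinical correlations (joint-adjusted, BH family):")
    print(top.round(3).to_string(index=False))

    # DAS28 across pathotypes
    lab = labels.loc[scores.index]
    graded = lab != Pathotype.UNGRADED.value
    overall, pairwise = cohort_stats.anova_bonferroni(
        clin.loc[graded.to_numpy(), "das28_esr_baseline"].to_numpy(), lab[graded].to_numpy()
    )
    print(f"\nDAS28-ESR across pathotypes: F={overall.statistic:.2f}, p={overall.p_value:.3g}")

    # progression by pathotype (lympho-myeloid vs rest)
    glab = labels[labels != Pathotype.UNGRADED.value]
    prog = bundle.outcomes.loc[glab.index, "progression"].astype(bool)
    lm = glab == Pathotype.LYMPHO_MYELOID.value
    table2 = [[int((lm & prog).sum()), int((lm & ~prog).sum())],
              [int((~lm & prog).sum()), int((~lm & ~prog).sum())]]
    fisher = cohort_stats.fisher_exact_2x2(table2)
    print(f"progression by pathotype {table2}: OR={fisher.statistic:.2f}, Fisher p={fisher.p_value:.4f}")

    # paired eigengene change in good responders with 6-month biopsies
    ids_6m = bundle.expression_6m.columns
    good = bundle.outcomes.loc[ids_6m, "eular_response"] == "good"
    paired_out = {}
    if good.sum() >= 3:
        gs_map = json.load(open(RESULTS / "gene_sets.json"))
        for name, genes in gs_map.items():
            both = pd.concat([bundle.expression_baseline.loc[:, ids_6m], bundle.expression_6m], axis=1)
            both.columns = [f"pre_{c}" for c in ids_6m] + [f"post_{c}" for c in ids_6m]
            sc = eigengene_score(both, GeneSet(name, tuple(genes)))
            pre = sc[[f"pre_{c}" for c in ids_6m[good]]].to_numpy()
            post = sc[[f"post_{c}" for c in ids_6m[good]]].to_numpy()
            res = cohort_stats.paired_change_test(pre, post)
            paired_out[name] = {"estimate": res.estimate, "p": res.p_value, "n_pairs": res.n_used}
            print(f"good responders, {name} eigengene change: {res.estimate:+.2f} (p={res.p_value:.3g}, n={res.n_used})")
    with open(RESULTS / "paired_change_good_responders.json", "w") as fh:
        json.dump(paired_out, fh, indent=2)


if __name__ == "__main__":
    main()
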