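#!/usr/bin/env python
"""Pathotype gene-panel construction and eigengene scoring.

Selects, per pathotype, the genes elevated against each of the other two
(pairwise moderated t, BH-adjusted p < 0.01), trims each set to the 50 genes
best correlated with its first principal component, and scores every sample
with the three module eigengenes adjusted for biopsy joint position.
"""

import json
from pathlib import Path

from synopath.histopathology import Pathotype
from synopath.signatures import (
    GeneSet,
    score_gene_sets,
    select_pathotype_genes,
    standardize_scores,
    top_k_by_pc1,
    group_score_table,
)
from synopath.simulate import read_bundle

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    bundle = read_bundle(RESULTS / "cohort")
    labels = pd.read_csv(RESULTS / "pathotype_labels.csv", index_col=0).iloc[:, 0]
    expr = bundle.expression_baseline
    lab = labels.loc[expr.columns]
    graded = (lab != Pathotype.UNGRADED.value).to_numpy()

    selected = select_pathotype_genes(expr.loc[:, graded], lab[graded], alpha=0.01)
    gene_sets = {
        name: top_k_by_pc1(expr.loc[:, graded], GeneSet(name, genes), k=50)
        for name, genes in selected.items()
        if genes
    }
    with open(RESULTS / "gene_sets.json", "w") as fh:
        json.dump({n: list(gs.genes) for n, gs in gene_sets.items()}, fh, indent=2)
    for name, genes in selected.items():
        print(f"{name}: {len(genes)} genes pass pairwise DE; panel keeps {len(gene_sets[name]) if name in gene_sets else 0}")

    joint = bundle.clinical["joint_category"].loc[expr.columns]
    scores = score_gene_sets(expr, gene_sets, joint=joint)
    scores.rename_axis("sample_id").to_csv(RESULTS / "eigengenes.csv")
    print("inter-eigengene correlations (expect lym-mye > 0, fib negative):")
    print(scores.corr().round(3).to_string())

    std = standardize_scores(scores)
    radar = group_score_table(std, lab.loc[scores.index])
    radar.to_csv(RESULTS / "eigengene_group_means.csv")
    print("standardized group means written to eigengene_group_means.csv")


if __name__ == "__main__":
    main()
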