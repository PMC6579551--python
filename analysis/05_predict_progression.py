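#!/usr/bin/env python
"""Radiographic-progression prediction with internal validation.

Backward stepwise logistic selection over 16 baseline clinical covariates,
then the gene screen (progressors vs nonprogressors, unadjusted p < 0.05)
feeding an L1-penalized logistic model (lambda by 10-fold CV) over screened
genes + surviving clinical covariates.  Discrimination is reported as
apparent and bootstrap optimism-corrected AUC with the whole recipe refit in
every resample.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from synopath.histopathology import Pathotype
from synopath.pipeline import CLINICAL_CANDIDATES
from synopath.progression import backward_stepwise_logistic, optimism_corrected_auc, screen_lasso_recipe
from synopath.simulate import read_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--boot", type=int, default=200, help="bootstrap repetitions")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    bundle = read_bundle(RESULTS / "cohort")
    labels = pd.read_csv(RESULTS / "pathotype_labels.csv", index_col=0).iloc[:, 0]
    expr = bundle.expression_baseline
    data = bundle.clinical.loc[expr.columns].join(bundle.outcomes.loc[expr.columns])
    data["gender_female"] = (data["gender"] == "F").astype(float)
    data["eular_good"] = (data["eular_response"] == "good").astype(float)
    data["eular_none"] = (data["eular_response"] == "none").astype(float)
    data["pathotype_lm"] = (labels.loc[expr.columns] == Pathotype.LYMPHO_MYELOID.value).astype(float)
    data["progression"] = data["progression"].astype(float)
    gene_cols = [f"g_{g}" for g in expr.index]
    genes_df = pd.DataFrame(expr.T.to_numpy(), index=data.index, columns=gene_cols)
    data = pd.concat([data, genes_df], axis=1)

    candidates = CLINICAL_CANDIDATES + ["gender_female", "eular_good", "eular_none", "pathotype_lm"]
    stepwise = backward_stepwise_logistic(data, candidates, "progression")
    print(f"stepwise clinical model keeps {len(stepwise.selected)}/16: {stepwise.selected}")
    print(f"  apparent AUC (clinical only): {stepwise.apparent_auc:.3f}")

    clinical_selected = stepwise.selected if stepwise.selected else candidates
    recipe = screen_lasso_recipe(gene_cols, clinical_selected, alpha_screen=0.05, n_folds=10)
    validation = optimism_corrected_auc(data, "progression", recipe, n_boot=args.boot, seed=args.seed)
    model = validation["model"]
    print(f"lasso model: lambda={model.lambda_:.4f}, {len(model.selected)} nonzero terms")
    print(f"  selected: {model.selected}")
    print(f"  apparent AUC {validation['apparent_auc']:.3f}, optimism {validation['optimism']:.3f}, "
          f"corrected AUC {validation['corrected_auc']:.3f} ({args.boot} resamples)")

    report = {
        "stepwise": {"selected": stepwise.selected, "apparent_auc": stepwise.apparent_auc},
        "lasso": {
            "selected": model.selected,
            "coefficients": {k: v for k, v in model.coefficients.items() if v != 0.0},
            "lambda": model.lambda_,
        },
        "apparent_auc": validation["apparent_auc"],
        "optimism": validation["optimism"],
        "corrected_auc": validation["corrected_auc"],
        "n_boot": args.boot,
        "seed": args.seed,
    }
    with open(RESULTS / "progression_model.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
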