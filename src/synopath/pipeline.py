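"""End-to-end orchestration: simulate (or ingest) -> pathotype classification
-> gene panels and eigengenes -> clinical associations -> progression model.

Every stage writes plain CSV/JSON into the output directory so any stage can
be re-run or inspected in isolation, and the JSON summary of a run is
byte-identical under a fixed config and seed (timings excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, histopathology, progression, signatures
from .histopathology import Pathotype, RuleConfig
from .simulate import CohortBundle, GeneratorConfig, generate_cohort, read_bundle, write_bundle

logger = logging.getLogger("synopath")

CLINICAL_CANDIDATES = [
    "age",
    "symptom_duration",
    "esr",
    "crp",
    "rf_titre",
    "acpa_titre",
    "vas",
    "tjc",
    "sjc",
    "das28_esr_baseline",
    "haq",
    "us_st_max",
    "us_pd_max",
]
# plus gender, EULAR response and pathotype encoded below: 16 candidates


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_dir: str | None = None  # read a written bundle instead of simulating
    rules: RuleConfig = field(default_factory=RuleConfig)
    alpha_de: float = 0.01
    alpha_screen: float = 0.05
    top_k: int = 50
    n_folds: int = 10
    n_boot: int = 500
    penalize_clinical: bool = True
    seed: int = 0
    out_dir: str = "synopath_run"

    def validate(self) -> "RunConfig":
        for name in ("alpha_de", "alpha_screen"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must lie in (0,1)")
        for name in ("top_k", "n_folds", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        return self


def _config_hash(cfg: RunConfig) -> str:
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir", None)  # location does not affect the analysis
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return run
    return wrap


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the JSON-serializable summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    summary: dict = {"seed": cfg.seed, "config_hash": _config_hash(cfg)}
    try:
        bundle = _stage("simulate")(_load_or_simulate)(cfg, out)
        labels, pathotype_summary = _stage("classify")(_classify)(bundle, cfg, out)
        summary["pathotypes"] = pathotype_summary
        sig = _stage("signatures")(_signatures)(bundle, labels, cfg, out)
        summary.update(sig["summary"])
        assoc = _stage("associate")(_associations)(bundle, labels, sig["scores"], cfg, out)
        summary.update(assoc)
        pred = _stage("predict")(_predict)(bundle, labels, cfg, out)
        summary.update(pred)
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def _load_or_simulate(cfg: RunConfig, out: Path) -> CohortBundle:
    if cfg.input_dir is not None:
        path = Path(cfg.input_dir)
        if not (path / "manifest.json").exists():
            raise FileNotFoundError(f"no bundle manifest at {path}")
        return read_bundle(path)
    generator = dataclasses.replace(cfg.generator, seed=cfg.seed)
    bundle = generate_cohort(generator)
    write_bundle(bundle, out / "cohort")
    return bundle


def _classify(bundle: CohortBundle, cfg: RunConfig, out: Path):
    labels = histopathology.classify_samples(bundle.ihc, cfg.rules)
    labels.rename_axis("sample_id").to_csv(out / "labels.csv")
    summary = histopathology.summarize_pathotypes(labels.tolist())
    return labels, {
        "n_total": summary.n_total,
        "n_graded": summary.n_graded,
        "counts": summary.counts,
        "percent": summary.percent,
        "graded_percent": summary.graded_percent,
    }


def _signatures(bundle: CohortBundle, labels: pd.Series, cfg: RunConfig, out: Path):
    expr = bundle.expression_baseline
    expr_labels = labels.loc[expr.columns]
    graded = expr_labels != Pathotype.UNGRADED.value
    expr_graded = expr.loc[:, graded.to_numpy()]
    selected = signatures.select_pathotype_genes(expr_graded, expr_labels[graded], alpha=cfg.alpha_de)
    gene_sets = {}
    for name, genes in selected.items():
        if genes:
            gs = signatures.GeneSet(name, genes)
            gene_sets[name] = signatures.top_k_by_pc1(expr_graded, gs, cfg.top_k)
    with open(out / "gene_sets.json", "w") as fh:
        json.dump({n: list(gs.genes) for n, gs in gene_sets.items()}, fh, indent=2)
    joint = bundle.clinical["joint_category"].loc[expr.columns]
    counts = joint.value_counts()
    joint_ok = joint if (counts >= 2).all() else None
    scores = (
        signatures.score_gene_sets(expr, gene_sets, joint=joint_ok)
        if gene_sets
        else pd.DataFrame(index=expr.columns)
    )
    scores.rename_axis("sample_id").to_csv(out / "eigengenes.csv")
    summary = {"gene_set_sizes": {n: len(gs) for n, gs in gene_sets.items()}}
    if scores.shape[1] >= 2:
        summary["eigengene_correlations"] = {
            f"{a}~{b}": float(scores[a].corr(scores[b]))
            for i, a in enumerate(scores.columns)
            for b in scores.columns[i + 1 :]
        }
    return {"scores": scores, "gene_sets": gene_sets, "summary": summary}


def _associations(bundle: CohortBundle, labels: pd.Series, scores: pd.DataFrame, cfg: RunConfig, out: Path):
    summary: dict = {}
    clin = bundle.clinical
    results = []
    clin_vars = ["das28_esr_baseline", "esr", "crp", "rf_titre", "acpa_titre", "us_st_bj", "us_pd_bj", "haq"]
    for module in scores.columns:
        for var in clin_vars:
            x = scores[module].to_numpy()
            y = clin.loc[scores.index, var].to_numpy(dtype=float)
            joint = clin.loc[scores.index, "joint_category"].to_numpy()
            res = cohort_stats.spearman_adjusted(x, y, joint, label=f"{module}~{var}")
            results.append(res)
    if results:
        cohort_stats.adjust_family(results)
        table = pd.DataFrame(
            [
                {"label": r.label, "rho": r.statistic, "p_value": r.p_value, "adj_p": r.adj_p, "n": r.n_used}
                for r in results
            ]
        )
        table.to_csv(out / "assoc_results.csv", index=False)
        summary["eigengene_clinical_correlations"] = {
            r.label: {"rho": round(r.statistic, 6), "p": round(r.p_value, 8), "adj_p": round(r.adj_p, 8)}
            for r in results
        }

    # progression-by-pathotype Fisher test (lympho-myeloid vs the rest)
    graded = labels[labels != Pathotype.UNGRADED.value]
    prog = bundle.outcomes.loc[graded.index, "progression"].astype(bool)
    lm = graded == Pathotype.LYMPHO_MYELOID.value
    table2 = np.array(
        [
            [int((lm & prog).sum()), int((lm & ~prog).sum())],
            [int((~lm & prog).sum()), int((~lm & ~prog).sum())],
        ]
    )
    if prog.any() and (~prog).any():
        fisher = cohort_stats.fisher_exact_2x2(table2)
        summary["fisher_progression"] = {
            "table": table2.tolist(),
            "odds_ratio": None if not np.isfinite(fisher.statistic) else round(fisher.statistic, 6),
            "p_value": round(fisher.p_value, 8),
        }

    # paired pre/post eigengene change in good responders
    if scores.shape[1] and bundle.expression_6m.shape[1] >= 3:
        ids_6m = bundle.expression_6m.columns
        good = bundle.outcomes.loc[ids_6m, "eular_response"] == "good"
        paired = {}
        if good.sum() >= 3:
            gene_sets = {c: None for c in scores.columns}
            with open(out / "gene_sets.json") as fh:
                gs_map = json.load(fh)
            for name in gene_sets:
                gs = signatures.GeneSet(name, tuple(gs_map[name]))
                both = pd.concat(
                    [bundle.expression_baseline.loc[:, ids_6m], bundle.expression_6m], axis=1
                )
                both.columns = [f"pre_{c}" for c in ids_6m] + [f"post_{c}" for c in ids_6m]
                sc = signatures.eigengene_score(both, gs)
                pre = sc[[f"pre_{c}" for c in ids_6m[good]]].to_numpy()
                post = sc[[f"post_{c}" for c in ids_6m[good]]].to_numpy()
                res = cohort_stats.paired_change_test(pre, post)
                paired[name] = {"estimate": round(res.estimate, 6), "p_value": round(res.p_value, 8)}
        summary["paired_change_good_responders"] = paired
    return summary


def _predict(bundle: CohortBundle, labels: pd.Series, cfg: RunConfig, out: Path):
    expr = bundle.expression_baseline
    data = bundle.clinical.loc[expr.columns].copy()
    data = data.join(bundle.outcomes.loc[expr.columns])
    data["gender_female"] = (data["gender"] == "F").astype(float)
    data["eular_good"] = (data["eular_response"] == "good").astype(float)
    data["eular_none"] = (data["eular_response"] == "none").astype(float)
    data["pathotype_lm"] = (labels.loc[expr.columns] == Pathotype.LYMPHO_MYELOID.value).astype(float)
    data["progression"] = data["progression"].astype(float)
    gene_cols = [f"g_{g}" for g in expr.index]
    genes_df = pd.DataFrame(expr.T.to_numpy(), index=data.index, columns=gene_cols)
    data = pd.concat([data, genes_df], axis=1)

    candidates = CLINICAL_CANDIDATES + ["gender_female", "eular_good", "eular_none", "pathotype_lm"]
    stepwise = progression.backward_stepwise_logistic(data, candidates, "progression")
    clinical_selected = stepwise.selected if stepwise.selected else candidates

    recipe = progression.screen_lasso_recipe(
        gene_cols,
        clinical_selected,
        alpha_screen=cfg.alpha_screen,
        n_folds=cfg.n_folds,
        penalize_clinical=cfg.penalize_clinical,
    )
    validation = progression.optimism_corrected_auc(data, "progression", recipe, n_boot=cfg.n_boot, seed=cfg.seed)
    model = validation["model"]

    report = {
        "stepwise_clinical": {
            "selected": stepwise.selected,
            "apparent_auc": round(stepwise.apparent_auc, 6),
        },
        "lasso": {
            "selected": model.selected,
            "coefficients": {k: round(v, 6) for k, v in model.coefficients.items() if v != 0.0},
            "lambda": round(model.lambda_, 6),
        },
        "apparent_auc": round(validation["apparent_auc"], 6),
        "corrected_auc": round(validation["corrected_auc"], 6),
        "optimism": round(validation["optimism"], 6),
        "n_boot": validation["n_boot"],
    }
    with open(out / "model_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return {"prediction": report}
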