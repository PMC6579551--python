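"""Synthetic early-RA cohort generator.

Emulates the statistical structure of a treatment-naive early rheumatoid
arthritis biopsy cohort so the full analysis pipeline is testable without
patient data: a three-pathotype mixture (lympho-myeloid / diffuse-myeloid /
pauci-immune-fibroid), per-patient latent module factors (lymphoid, myeloid,
fibroid) whose class means plant pathotype-specific expression modules on
the log2 scale, residually correlated so lymphoid-myeloid is positive and
fibroid negative to both; semiquantitative IHC grades whose rule-based
classification recovers the latent class with configurable fidelity;
clinical covariates driven linearly by the inflammatory factors; a 6-month
follow-up in which responders' inflammatory factors relax toward the
population mean; and a radiographic-progression outcome drawn from a
logistic model on the lymphoid factor and log RF titre.

All randomness flows from one seed through named child seeds, so a bundle
is bit-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import validate_expression, write_expression, read_expression
from .histopathology import IHCScores, Pathotype, read_ihc, write_ihc

__all__ = ["GeneratorConfig", "CohortBundle", "ConfigError", "generate_cohort", "write_bundle", "read_bundle"]

CLASSES = (Pathotype.LYMPHO_MYELOID, Pathotype.DIFFUSE_MYELOID, Pathotype.PAUCI_IMMUNE_FIBROID)
MODULES = ("lymphoid", "myeloid", "fibroid")

# latent factor mean per class, in units of module_shift: the module's genes
# are elevated by one full module_shift in the module's own class, elevated
# by a third of it for myeloid in the lympho-myeloid class (lymphoid-rich
# tissue also carries myeloid infiltrate), and mildly depressed elsewhere.
_CLASS_FACTOR_MEANS = {
    Pathotype.LYMPHO_MYELOID: np.array([1.0, 1.0 / 3.0, -0.5]),
    Pathotype.DIFFUSE_MYELOID: np.array([-0.25, 1.0, -0.5]),
    Pathotype.PAUCI_IMMUNE_FIBROID: np.array([-0.25, -0.5, 1.0]),
}


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the printed cohort structure: 144 recruited, 89.6%
    gradeable, class mixing 51/44/34 among 129 graded, a 242-gene targeted
    panel (3 x 50 pathotype-module genes + 92 background), wrist-dominant
    biopsy joints, and a ~16% radiographic-progression rate driven by the
    lymphoid factor and RF titre.
    """

    n_recruited: int = 144
    graded_fraction: float = 129.0 / 144.0
    class_probs: tuple[float, float, float] = (51 / 129, 44 / 129, 34 / 129)
    n_genes_per_module: int = 50
    n_background_genes: int = 92
    module_shift: float = 2.0  # log2 units: ~4-fold elevation in own class
    inter_module_corr: tuple[float, float, float] = (0.4, -0.3, -0.3)  # (lym-mye, fib-lym, fib-mye)
    noise_sd: float = 1.0
    ihc_fidelity: float = 0.95
    # additive effects of (myeloid, lymphoid) latent factors on clinical covariates
    clinical_effect: dict = field(
        default_factory=lambda: {
            "das28_esr_baseline": (0.5, 0.25),
            "esr": (12.0, 6.0),
            "crp": (10.0, 4.0),
            "us_st": (0.4, 0.3),
            "us_pd": (0.4, 0.3),
        }
    )
    rf_lymphoid_effect: float = 0.8  # on log RF titre
    acpa_lymphoid_effect: float = 0.9  # on log ACPA titre
    # logistic model for progression: intercept + b_lym * f_lym + b_rf * z(log RF)
    progression_effect: dict = field(
        default_factory=lambda: {"intercept": -2.2, "lymphoid": 0.4, "rf": 0.35}
    )
    treatment_effect: float = 0.8  # fractional relaxation of inflammatory factors in good responders
    response_effect: tuple[float, float] = (0.45, 0.2)  # (myeloid, lymphoid) on DAS28 improvement
    joint_probs: dict = field(
        default_factory=lambda: {"wrist": 0.65, "mcp": 0.15, "knee": 0.12, "elbow": 0.08}
    )
    joint_effect: float = 0.2  # additive log2 shift of all genes per non-wrist joint category
    expr_baseline_fraction: float = 111.0 / 129.0
    expr_6m_fraction: float = 68.0 / 111.0
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_recruited < 10:
            raise ConfigError(f"n_recruited={self.n_recruited} must be >= 10")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or np.any(probs > 1):
            raise ConfigError(f"class_probs={self.class_probs} entries must lie in [0,1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError(f"class_probs={self.class_probs} must sum to 1 within 1e-12")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd={self.noise_sd} must be > 0")
        if not 0 < self.graded_fraction <= 1:
            raise ConfigError(f"graded_fraction={self.graded_fraction} must lie in (0,1]")
        if not 0 <= self.ihc_fidelity <= 1:
            raise ConfigError(f"ihc_fidelity={self.ihc_fidelity} must lie in [0,1]")
        if self.n_genes_per_module < 1:
            raise ConfigError(f"n_genes_per_module={self.n_genes_per_module} must be >= 1")
        if self.n_background_genes < 0:
            raise ConfigError(f"n_background_genes={self.n_background_genes} must be >= 0")
        r_lm, r_fl, r_fm = self.inter_module_corr
        corr = np.array([[1.0, r_lm, r_fl], [r_lm, 1.0, r_fm], [r_fl, r_fm, 1.0]])
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ConfigError(f"inter_module_corr={self.inter_module_corr} is not positive definite")
        if not 0 < self.expr_baseline_fraction <= 1 or not 0 < self.expr_6m_fraction <= 1:
            raise ConfigError("expr_baseline_fraction and expr_6m_fraction must lie in (0,1]")
        if abs(sum(self.joint_probs.values()) - 1.0) > 1e-9 or min(self.joint_probs.values()) < 0:
            raise ConfigError(f"joint_probs={self.joint_probs} must be a probability distribution")
        return self


@dataclass
class CohortBundle:
    expression_baseline: pd.DataFrame  # genes x samples, log2
    expression_6m: pd.DataFrame  # genes x subset of baseline samples
    ihc: list[IHCScores]
    clinical: pd.DataFrame  # indexed by sample_id
    outcomes: pd.DataFrame  # indexed by sample_id
    truth: pd.DataFrame  # latent class / factors / progression prob, recovery tests only
    config: GeneratorConfig

    def validate(self) -> "CohortBundle":
        ids = self.clinical.index
        if ids.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if not self.outcomes.index.equals(ids) or not self.truth.index.equals(ids):
            raise ValueError("clinical/outcomes/truth sample identifiers are inconsistent")
        if not set(self.expression_baseline.columns) <= set(ids):
            raise ValueError("expression samples not a subset of cohort samples")
        if not set(self.expression_6m.columns) <= set(self.expression_baseline.columns):
            raise ValueError("6-month expression samples not a subset of baseline expression samples")
        validate_expression(self.expression_baseline)
        if self.expression_6m.shape[1] > 0:
            validate_expression(self.expression_6m)
        return self


def _child_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return {name: np.random.default_rng(child) for name, child in zip(names, ss.spawn(len(names)))}


_STAGES = ["class", "factors", "expression", "ihc", "clinical", "outcomes", "followup", "subset"]


def _ihc_prototype(cls: Pathotype, rng: np.random.Generator) -> dict:
    """Draw grades from the class's rule-consistent region."""
    if cls is Pathotype.LYMPHO_MYELOID:
        return {
            "cd20": int(rng.integers(2, 5)),
            "cd3": int(rng.integers(2, 5)),
            "cd68_sublining": int(rng.integers(2, 5)),
            "cd68_lining": int(rng.integers(1, 5)),
            "cd138": int(rng.integers(2, 5)),
            "aggregate_grade": int(rng.integers(2, 4)),
        }
    if cls is Pathotype.DIFFUSE_MYELOID:
        return {
            "cd20": int(rng.integers(0, 2)),
            "cd3": int(rng.integers(0, 5)),
            "cd68_sublining": int(rng.integers(2, 5)),
            "cd68_lining": int(rng.integers(1, 5)),
            "cd138": int(rng.integers(0, 3)),
            "aggregate_grade": int(rng.integers(0, 2)),
        }
    return {
        "cd20": 0,
        "cd3": 0,
        "cd68_sublining": int(rng.integers(0, 2)),
        "cd68_lining": int(rng.integers(0, 3)),
        "cd138": 0,
        "aggregate_grade": 0,
    }


def _discretize_factor(value: float, lo: float = -2.0, hi: float = 4.0, levels: int = 5) -> int:
    bins = np.linspace(lo, hi, levels + 1)[1:-1]
    return int(np.digitize(value, bins))


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate a complete synthetic cohort bundle; deterministic per seed."""
    config.validate()
    rngs = _child_rngs(config.seed, _STAGES)
    n = config.n_recruited
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    s = config.module_shift

    # latent class and gradeability
    classes = [CLASSES[i] for i in rngs["class"].choice(3, size=n, p=np.asarray(config.class_probs))]
    gradeable = rngs["class"].random(n) < config.graded_fraction

    # latent module factors: class mean + correlated residual
    r_lm, r_fl, r_fm = config.inter_module_corr
    corr = np.array([[1.0, r_lm, r_fl], [r_lm, 1.0, r_fm], [r_fl, r_fm, 1.0]])
    chol = np.linalg.cholesky(corr)
    resid = rngs["factors"].standard_normal((n, 3)) @ chol.T
    mu = np.vstack([_CLASS_FACTOR_MEANS[c] for c in classes]) * s
    factors = mu + resid  # columns: lymphoid, myeloid, fibroid
    f_lym, f_mye, f_fib = factors[:, 0], factors[:, 1], factors[:, 2]

    # biopsied joint category with a small additive expression offset
    joints = list(config.joint_probs)
    joint_cat = rngs["clinical"].choice(joints, size=n, p=[config.joint_probs[j] for j in joints])
    joint_offset = np.array([config.joint_effect * joints.index(j) for j in joint_cat])

    # expression: per-gene baseline + module factor + joint offset + noise
    genes = (
        [f"LYM{i + 1:03d}" for i in range(config.n_genes_per_module)]
        + [f"MYE{i + 1:03d}" for i in range(config.n_genes_per_module)]
        + [f"FIB{i + 1:03d}" for i in range(config.n_genes_per_module)]
        + [f"BG{i + 1:03d}" for i in range(config.n_background_genes)]
    )
    n_genes = len(genes)
    rng_e = rngs["expression"]
    baseline_level = rng_e.uniform(6.0, 12.0, size=n_genes)
    module_of_gene = np.repeat([0, 1, 2, -1], [config.n_genes_per_module] * 3 + [config.n_background_genes])
    signal = np.zeros((n_genes, n))
    for m in range(3):
        signal[module_of_gene == m] = factors[:, m]
    expr = (
        baseline_level[:, None]
        + signal
        + joint_offset[None, :]
        + rng_e.normal(0.0, config.noise_sd, size=(n_genes, n))
    )
    expression_all = pd.DataFrame(expr, index=genes, columns=sample_ids)

    # IHC grades: factor-driven ordinal draws, clamped into the latent class's
    # rule region with probability ihc_fidelity (rule-boundary cases otherwise)
    rng_i = rngs["ihc"]
    ihc_list = []
    for i, sid in enumerate(sample_ids):
        faithful = rng_i.random() < config.ihc_fidelity
        if faithful:
            grades = _ihc_prototype(classes[i], rng_i)
        else:
            grades = {
                "cd20": _discretize_factor(f_lym[i] + rng_i.normal(0, 1)),
                "cd3": _discretize_factor(f_lym[i] + rng_i.normal(0, 1)),
                "cd138": _discretize_factor(f_lym[i] + rng_i.normal(0, 1)),
                "cd68_sublining": _discretize_factor(f_mye[i] + rng_i.normal(0, 1)),
                "cd68_lining": _discretize_factor(f_mye[i] + rng_i.normal(0, 1)),
                "aggregate_grade": min(3, _discretize_factor(f_lym[i] + rng_i.normal(0, 1))),
            }
        ihc_list.append(IHCScores(sample_id=sid, gradeable=bool(gradeable[i]), **grades))

    # clinical covariates, linear in the inflammatory factors
    rng_c = rngs["clinical"]
    eff = config.clinical_effect
    das28 = np.clip(5.6 + eff["das28_esr_baseline"][0] * f_mye + eff["das28_esr_baseline"][1] * f_lym + rng_c.normal(0, 0.8, n), 1.0, 9.5)
    esr = np.clip(30 + eff["esr"][0] * f_mye + eff["esr"][1] * f_lym + rng_c.normal(0, 10, n), 2.0, 120.0)
    crp = np.clip(12 + eff["crp"][0] * f_mye + eff["crp"][1] * f_lym + rng_c.normal(0, 8, n), 0.2, 200.0)
    log_rf = 3.0 + config.rf_lymphoid_effect * f_lym + rng_c.normal(0, 1.0, n)
    rf_titre = np.exp(log_rf)
    acpa_titre = np.exp(3.5 + config.acpa_lymphoid_effect * f_lym + rng_c.normal(0, 1.2, n))
    vas = np.clip(55 + 5 * f_mye + rng_c.normal(0, 18, n), 0, 100)
    sjc = np.clip(np.round(7 + 2 * f_mye + rng_c.normal(0, 3, n)), 0, 28).astype(int)
    tjc = np.clip(np.round(9 + 2 * f_mye + rng_c.normal(0, 4, n)), 0, 28).astype(int)
    haq = np.clip(1.2 + 0.25 * f_mye + rng_c.normal(0, 0.5, n), 0, 3)
    us_st_bj = np.clip(1.5 + eff["us_st"][0] * f_mye + eff["us_st"][1] * f_lym + rng_c.normal(0, 0.5, n), 0, 3)
    us_pd_bj = np.clip(1.2 + eff["us_pd"][0] * f_mye + eff["us_pd"][1] * f_lym + rng_c.normal(0, 0.5, n), 0, 3)
    us_st_max = np.clip(us_st_bj + np.abs(rng_c.normal(0, 0.4, n)), 0, 3)
    us_pd_max = np.clip(us_pd_bj + np.abs(rng_c.normal(0, 0.4, n)), 0, 3)
    serum_cxcl13 = np.exp(4.0 + 0.7 * f_lym + 0.3 * f_mye + rng_c.normal(0, 0.8, n))
    serum_mmp3 = np.exp(3.5 + 0.5 * f_mye + rng_c.normal(0, 0.7, n))
    serum_sicam1 = np.exp(5.5 + 0.15 * f_mye + rng_c.normal(0, 0.5, n))
    serum_il8 = np.exp(2.5 + 0.1 * f_mye + rng_c.normal(0, 0.8, n))
    symptom_duration = np.clip(rng_c.normal(5.6, 3.2, n), 0.5, 12.0)
    age = np.clip(np.round(rng_c.normal(54, 13, n)), 18, 90).astype(int)
    gender = rng_c.choice(["F", "M"], size=n, p=[0.72, 0.28])

    clinical = pd.DataFrame(
        {
            "joint_category": joint_cat,
            "gender": gender,
            "age": age,
            "symptom_duration": symptom_duration,
            "das28_esr_baseline": das28,
            "esr": esr,
            "crp": crp,
            "rf_titre": rf_titre,
            "acpa_titre": acpa_titre,
            "vas": vas,
            "tjc": tjc,
            "sjc": sjc,
            "haq": haq,
            "us_st_bj": us_st_bj,
            "us_pd_bj": us_pd_bj,
            "us_st_max": us_st_max,
            "us_pd_max": us_pd_max,
            "serum_cxcl13": serum_cxcl13,
            "serum_sicam1": serum_sicam1,
            "serum_mmp3": serum_mmp3,
            "serum_il8": serum_il8,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # 6-month response: higher inflammatory factors -> larger DAS28 improvement
    rng_o = rngs["outcomes"]
    b_mye, b_lym = config.response_effect
    improvement = 1.8 + b_mye * f_mye + b_lym * f_lym + rng_o.normal(0, 1.1, n)
    das28_6m = np.clip(das28 - improvement, 0.2, 10.0)
    from .cohort_stats import eular_response

    eular = np.array([eular_response(b, f) for b, f in zip(das28, das28_6m)])

    # radiographic progression from lymphoid factor + RF titre
    pe = config.progression_effect
    z_log_rf = (log_rf - log_rf.mean()) / log_rf.std(ddof=0)
    lin = pe["intercept"] + pe["lymphoid"] * f_lym + pe["rf"] * z_log_rf
    prog_prob = 1.0 / (1.0 + np.exp(-lin))
    progression = rng_o.random(n) < prog_prob
    delta_shss = np.where(progression, 1 + rng_o.poisson(1.5, n), 0).astype(int)

    outcomes = pd.DataFrame(
        {
            "das28_esr_6m": das28_6m,
            "eular_response": eular,
            "delta_shss": delta_shss,
            "progression": progression,
        },
        index=clinical.index,
    )

    # follow-up expression: responders' inflammatory factors relax toward the
    # population mean; fibroid rises in good responders; nonresponders show a
    # muted lymphoid decrease only
    rng_f = rngs["followup"]
    te = config.treatment_effect
    post_factors = factors.copy()
    good = eular == "good"
    none = eular == "none"
    post_factors[good, 0] *= 1.0 - te
    post_factors[good, 1] *= 1.0 - te
    post_factors[good, 2] += te * 0.5
    post_factors[none, 0] *= 1.0 - te / 2.0

    rng_s = rngs["subset"]
    graded_ids = [sid for sid, g in zip(sample_ids, gradeable) if g]
    n_expr = max(2, int(round(config.expr_baseline_fraction * len(graded_ids))))
    expr_ids = sorted(rng_s.choice(graded_ids, size=min(n_expr, len(graded_ids)), replace=False).tolist())
    expression_baseline = expression_all.loc[:, expr_ids]

    n_6m = int(round(config.expr_6m_fraction * len(expr_ids)))
    ids_6m = sorted(rng_s.choice(expr_ids, size=n_6m, replace=False).tolist()) if n_6m > 0 else []
    signal_post = np.zeros((n_genes, n))
    for m in range(3):
        signal_post[module_of_gene == m] = post_factors[:, m]
    expr_post = (
        baseline_level[:, None]
        + signal_post
        + joint_offset[None, :]
        + rng_f.normal(0.0, config.noise_sd, size=(n_genes, n))
    )
    expression_6m = pd.DataFrame(expr_post, index=genes, columns=sample_ids).loc[:, ids_6m]

    truth = pd.DataFrame(
        {
            "latent_class": [c.value for c in classes],
            "factor_lymphoid": f_lym,
            "factor_myeloid": f_mye,
            "factor_fibroid": f_fib,
            "post_factor_lymphoid": post_factors[:, 0],
            "post_factor_myeloid": post_factors[:, 1],
            "post_factor_fibroid": post_factors[:, 2],
            "progression_prob": prog_prob,
        },
        index=clinical.index,
    )

    bundle = CohortBundle(
        expression_baseline=expression_baseline,
        expression_6m=expression_6m,
        ihc=ihc_list,
        clinical=clinical,
        outcomes=outcomes,
        truth=truth,
        config=config,
    )
    return bundle.validate()


def write_bundle(bundle: CohortBundle, directory) -> dict:
    """Write the bundle as CSVs plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expression_baseline, directory / "expression.csv")
    write_expression(bundle.expression_6m, directory / "expression_6m.csv")
    write_ihc(bundle.ihc, directory / "ihc.csv")
    bundle.clinical.to_csv(directory / "clinical.csv")
    bundle.outcomes.to_csv(directory / "outcomes.csv")
    bundle.truth.to_csv(directory / "truth.csv")
    manifest = {
        "files": [
            "expression.csv",
            "expression_6m.csv",
            "ihc.csv",
            "clinical.csv",
            "outcomes.csv",
            "truth.csv",
        ],
        "seed": bundle.config.seed,
        "config": dataclasses.asdict(bundle.config),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_bundle(directory) -> CohortBundle:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = manifest["config"]
    cfg_dict["class_probs"] = tuple(cfg_dict["class_probs"])
    cfg_dict["inter_module_corr"] = tuple(cfg_dict["inter_module_corr"])
    cfg_dict["response_effect"] = tuple(cfg_dict["response_effect"])
    cfg_dict["clinical_effect"] = {k: tuple(v) for k, v in cfg_dict["clinical_effect"].items()}
    config = GeneratorConfig(**cfg_dict)
    clinical = pd.read_csv(directory / "clinical.csv", index_col="sample_id")
    outcomes = pd.read_csv(directory / "outcomes.csv", index_col="sample_id")
    truth = pd.read_csv(directory / "truth.csv", index_col="sample_id")
    bundle = CohortBundle(
        expression_baseline=read_expression(directory / "expression.csv"),
        expression_6m=read_expression(directory / "expression_6m.csv"),
        ihc=read_ihc(directory / "ihc.csv"),
        clinical=clinical,
        outcomes=outcomes,
        truth=truth,
        config=config,
    )
    return bundle.validate()
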