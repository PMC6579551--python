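"""Pathotype-specific gene panels and module eigengene scores.

A pathotype's gene set contains the genes significantly elevated in that
pathotype against *each* of the other two (pairwise empirical-Bayes
moderated t-tests, Benjamini-Hochberg adjusted within each pairwise
comparison, adjusted p below ``alpha`` and a positive log fold change in
both contrasts).  The elevation-sign requirement makes the three sets
disjoint: a gene cannot be elevated in two classes against each other.

The module *eigengene* is the first principal component of the per-gene
z-scored expression of the set across samples, signed so that it correlates
positively with the mean z-scored module expression.  Where a biopsy
joint-position category is supplied, scores are residualized against
joint-category indicators by least squares (the published adjustment for
biopsy joint position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import moderated_ttest, validate_expression, zscore_per_gene
from .histopathology import Pathotype

__all__ = [
    "GeneSet",
    "select_pathotype_genes",
    "top_k_by_pc1",
    "eigengene_score",
    "score_gene_sets",
    "standardize_scores",
]

# pathotype -> conventional module name
MODULE_NAMES = {
    Pathotype.LYMPHO_MYELOID: "lymphoid",
    Pathotype.DIFFUSE_MYELOID: "myeloid",
    Pathotype.PAUCI_IMMUNE_FIBROID: "fibroid",
}


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


def _aligned_labels(mat: pd.DataFrame, labels) -> pd.Series:
    labels = pd.Series(labels)
    missing = [s for s in mat.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without pathotype labels: {missing}")
    lab = labels.loc[mat.columns].map(lambda v: Pathotype(v))
    return lab


def select_pathotype_genes(
    mat: pd.DataFrame,
    labels,
    alpha: float = 0.01,
    *,
    moderated: bool = True,
) -> dict:
    """Pairwise DE selection of pathotype-elevated genes.

    Returns a dict mapping module name (lymphoid / myeloid / fibroid) to the
    (possibly empty) tuple of selected genes; a :class:`GeneSet` is only
    constructed downstream for non-empty selections.  UNGRADED samples are
    excluded before testing.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    validate_expression(mat)
    lab = _aligned_labels(mat, labels)
    keep = lab != Pathotype.UNGRADED
    mat = mat.loc[:, keep.to_numpy()]
    lab = lab[keep]
    classes = list(MODULE_NAMES)
    for p in classes:
        if (lab == p).sum() < 2:
            raise ValueError(f"pathotype {p.value} has fewer than 2 samples")

    # one DE table per unordered pair, oriented per pair order
    pair_results: dict[tuple, pd.DataFrame] = {}
    for i, p in enumerate(classes):
        for q in classes[i + 1 :]:
            mask = lab.isin([p, q]).to_numpy()
            sub = mat.loc[:, mask]
            groups = lab[mask].map(lambda v: v.value)
            # force orientation: log_fc = mean(p) - mean(q)
            ordered = sub.columns[groups.loc[sub.columns] == p.value].tolist() + sub.columns[
                groups.loc[sub.columns] == q.value
            ].tolist()
            sub = sub.loc[:, ordered]
            res = (
                moderated_ttest(sub, groups.loc[ordered])
                if moderated
                else moderated_ttest(sub, groups.loc[ordered], prior_df=0.0, prior_var=1.0)
            )
            pair_results[(p, q)] = res.set_index("gene")

    def oriented(p: Pathotype, q: Pathotype) -> pd.DataFrame:
        if (p, q) in pair_results:
            return pair_results[(p, q)]
        flipped = pair_results[(q, p)].copy()
        flipped["log_fc"] = -flipped["log_fc"]
        flipped["t_stat"] = -flipped["t_stat"]
        return flipped

    out: dict[str, tuple] = {}
    for p in classes:
        others = [q for q in classes if q is not p]
        selected = None
        for q in others:
            res = oriented(p, q)
            sig = res["adj_p"] < alpha if alpha < 1 else res["adj_p"] <= 1
            hit = set(res.index[sig & (res["log_fc"] > 0)])
            selected = hit if selected is None else selected & hit
        out[MODULE_NAMES[p]] = tuple(g for g in mat.index if g in selected)
    return out


def top_k_by_pc1(mat: pd.DataFrame, gene_set: GeneSet, k: int, *, signed: bool = False) -> GeneSet:
    """Reduce a gene set to the k genes best correlated with its PC1.

    The submatrix is z-scored per gene, its first principal component across
    samples computed, and genes ranked by |Pearson correlation| of their
    z-scored profile with PC1 (signed correlation via ``signed=True``).
    Ties break deterministically by gene identifier.  If the set has at most
    k genes it is returned with identifier-sorted order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [g for g in gene_set.genes if g not in mat.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    genes = sorted(gene_set.genes)
    if len(genes) <= k:
        return GeneSet(gene_set.name, tuple(genes))
    sub = zscore_per_gene(mat.loc[genes])
    pc1 = _pc1_scores(sub.to_numpy())
    z = sub.to_numpy()
    pc_c = pc1 - pc1.mean()
    denom = np.linalg.norm(z - z.mean(axis=1, keepdims=True), axis=1) * np.linalg.norm(pc_c)
    corr = (z - z.mean(axis=1, keepdims=True)) @ pc_c / np.where(denom == 0, np.nan, denom)
    key = corr if signed else np.abs(corr)
    order = sorted(range(len(genes)), key=lambda i: (-key[i], genes[i]))
    chosen = sorted(genes[i] for i in order[:k])
    return GeneSet(gene_set.name, tuple(chosen))


def _pc1_scores(z: np.ndarray) -> np.ndarray:
    """First right singular vector (per-sample PC1 scores) of a genes x samples
    z-scored matrix, scaled by the singular value."""
    u, s, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True), full_matrices=False)
    return s[0] * vt[0]


def eigengene_score(
    mat: pd.DataFrame,
    gene_set: GeneSet,
    joint=None,
    *,
    adjust_before_pca: bool = False,
) -> pd.Series:
    """Per-sample module eigengene score (PC1 of z-scored module expression).

    Sign is stabilized against the mean z-scored module expression.  With a
    joint category per sample, scores are residualized on joint indicators
    (or, with ``adjust_before_pca``, every gene row is residualized before
    the PCA).
    """
    validate_expression(mat)
    missing = [g for g in gene_set.genes if g not in mat.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    joint_codes = None
    if joint is not None:
        joint = pd.Series(joint)
        missing_j = [s for s in mat.columns if s not in joint.index]
        if missing_j:
            raise ValueError(f"samples without joint category: {missing_j}")
        joint_codes = joint.loc[mat.columns].astype(str)
        counts = joint_codes.value_counts()
        if (counts < 2).any():
            small = counts.index[counts < 2].tolist()
            raise ValueError(f"joint categories with < 2 samples: {small}")

    sub = zscore_per_gene(mat.loc[list(gene_set.genes)])
    z = sub.to_numpy()
    if adjust_before_pca and joint_codes is not None:
        design = _joint_design(joint_codes)
        beta, *_ = np.linalg.lstsq(design, z.T, rcond=None)
        z = (z.T - design @ beta).T
    score = _pc1_scores(z)
    mean_profile = z.mean(axis=0)
    align = np.corrcoef(score, mean_profile)[0, 1] if np.std(mean_profile) > 0 and np.std(score) > 0 else 1.0
    if align < 0:
        score = -score
    result = pd.Series(score, index=mat.columns, name=gene_set.name)
    if joint_codes is not None and not adjust_before_pca:
        design = _joint_design(joint_codes)
        beta, *_ = np.linalg.lstsq(design, result.to_numpy(), rcond=None)
        result = pd.Series(result.to_numpy() - design @ beta, index=mat.columns, name=gene_set.name)
    if not np.isfinite(result.to_numpy()).all():
        raise ValueError("non-finite eigengene scores")
    return result


def _joint_design(joint_codes: pd.Series) -> np.ndarray:
    dummies = pd.get_dummies(joint_codes, drop_first=True).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(joint_codes)), dummies])


def score_gene_sets(mat: pd.DataFrame, gene_sets: dict, joint=None, **kwargs) -> pd.DataFrame:
    """Score several gene sets; returns samples x modules DataFrame."""
    cols = {}
    for name, gs in gene_sets.items():
        if not isinstance(gs, GeneSet):
            gs = GeneSet(name, tuple(gs))
        cols[name] = eigengene_score(mat, gs, joint=joint, **kwargs)
    return pd.DataFrame(cols)


def standardize_scores(scores: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each eigengene column to mean 0, SD 1 (radar-plot scale)."""
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    values = scores.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        offenders = scores.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance score columns: {offenders}")
    return pd.DataFrame(
        (values - values.mean(axis=0)) / sd, index=scores.index, columns=scores.columns
    )


def group_score_table(scores: pd.DataFrame, groups) -> pd.DataFrame:
    """Group mean +/- SEM of (standardized) eigengene scores, one row per group."""
    groups = pd.Series(groups).loc[scores.index]
    rows = []
    for g, idx in scores.groupby(groups).groups.items():
        block = scores.loc[idx]
        n = len(block)
        rows.append(
            {"group": g, "n": n}
            | {f"{c}_mean": block[c].mean() for c in scores.columns}
            | {f"{c}_sem": block[c].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan for c in scores.columns}
        )
    return pd.DataFrame(rows).set_index("group")
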