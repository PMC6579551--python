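"""Immunohistochemistry data model and the rule-based synovial pathotype classifier.

Synovial biopsies are graded semiquantitatively (0-4) for CD20+ B cells,
CD3+ T cells, CD68+ macrophages (lining and sublining layers) and CD138+
plasma cells, plus an ordinal grade (0-3) for the organisation of lymphoid
aggregates.  Samples with no intact lining layer are not gradeable.  Graded
samples are stratified into three pathotypes by priority-ordered rules:

1. lympho-myeloid: organised CD20+ aggregates (grade >= 2 with CD20 >= 2),
   or heavy plasma-cell infiltration (CD138 above the configured cut);
2. diffuse-myeloid: sublining macrophages CD68 >= 2 with scant B cells
   (CD20 <= 1) and CD138 <= 2;
3. pauci-immune-fibroid: CD68 sublining < 2 and CD3, CD20, CD138 all < 1.

Samples matching no rule (or not gradeable) are UNGRADED.  The cut-points
are exposed in :class:`RuleConfig` because the published wording of the
criteria admits more than one reading at the boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Pathotype",
    "IHCScores",
    "RuleConfig",
    "DEFAULT_RULES",
    "classify_pathotype",
    "classify_samples",
    "summarize_pathotypes",
    "read_ihc",
    "write_ihc",
]

IHC_COLUMNS = ["sample_id", "cd20", "cd3", "cd68_l", "cd68_sl", "cd138", "aggregate_grade", "gradeable"]


class Pathotype(str, Enum):
    LYMPHO_MYELOID = "lympho_myeloid"
    DIFFUSE_MYELOID = "diffuse_myeloid"
    PAUCI_IMMUNE_FIBROID = "pauci_immune_fibroid"
    UNGRADED = "ungraded"


@dataclass(frozen=True)
class RuleConfig:
    """Cut-points of the pathotype rules (all inclusive thresholds).

    ``lympho_cd138_min=3`` encodes "CD138 > 2"; setting it to 2 reproduces
    the alternative literal reading of the published criteria (which then
    overlaps rule 2 at CD138 = 2; the priority order resolves the overlap).
    """

    lympho_aggregate_min: int = 2
    lympho_cd20_min: int = 2
    lympho_cd138_min: int = 3
    myeloid_cd68sl_min: int = 2
    myeloid_cd20_max: int = 1
    myeloid_cd138_max: int = 2
    fibroid_cd68sl_below: int = 2
    fibroid_immune_below: int = 1


DEFAULT_RULES = RuleConfig()

_RANGES = {
    "cd20": (0, 4),
    "cd3": (0, 4),
    "cd68_lining": (0, 4),
    "cd68_sublining": (0, 4),
    "cd138": (0, 4),
    "aggregate_grade": (0, 3),
}


@dataclass(frozen=True)
class IHCScores:
    """Semiquantitative immunostaining grades for one biopsy."""

    sample_id: str
    cd20: int
    cd3: int
    cd68_lining: int
    cd68_sublining: int
    cd138: int
    aggregate_grade: int
    gradeable: bool = True

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValueError(f"{name} must be an integer, got {value!r}")
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}] for sample {self.sample_id}")


def classify_pathotype(ihc: IHCScores, rules: RuleConfig = DEFAULT_RULES) -> Pathotype:
    """Apply the pathotype rules in priority order; deterministic and total."""
    if not ihc.gradeable:
        return Pathotype.UNGRADED
    if (
        ihc.aggregate_grade >= rules.lympho_aggregate_min and ihc.cd20 >= rules.lympho_cd20_min
    ) or ihc.cd138 >= rules.lympho_cd138_min:
        return Pathotype.LYMPHO_MYELOID
    if (
        ihc.cd68_sublining >= rules.myeloid_cd68sl_min
        and ihc.cd20 <= rules.myeloid_cd20_max
        and ihc.cd138 <= rules.myeloid_cd138_max
    ):
        return Pathotype.DIFFUSE_MYELOID
    if (
        ihc.cd68_sublining < rules.fibroid_cd68sl_below
        and ihc.cd3 < rules.fibroid_immune_below
        and ihc.cd20 < rules.fibroid_immune_below
        and ihc.cd138 < rules.fibroid_immune_below
    ):
        return Pathotype.PAUCI_IMMUNE_FIBROID
    return Pathotype.UNGRADED


def classify_samples(scores: Iterable[IHCScores], rules: RuleConfig = DEFAULT_RULES) -> pd.Series:
    """Classify a collection of samples; returns labels indexed by sample_id."""
    scores = list(scores)
    labels = {s.sample_id: classify_pathotype(s, rules).value for s in scores}
    if len(labels) != len(scores):
        raise ValueError("duplicate sample identifiers in IHC scores")
    return pd.Series(labels, name="pathotype")


@dataclass
class PathotypeSummary:
    n_total: int
    n_graded: int
    counts: dict = field(default_factory=dict)
    proportions: dict | None = None  # among graded samples
    percent: dict | None = None  # nearest-integer percent among graded
    graded_percent: float | None = None
    failure_percent: float | None = None


def summarize_pathotypes(labels: Sequence[Pathotype | str]) -> PathotypeSummary:
    """Counts and proportions per pathotype among gradeable samples.

    Percentages are rounded for report output: class percentages to the
    nearest integer (among graded samples), graded/failure yield to one
    decimal place.  With zero graded samples proportions are absent.
    """
    labels = [Pathotype(l) for l in labels]
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(labels)
    n_total = len(labels)
    n_graded = n_total - counts.get(Pathotype.UNGRADED, 0)
    summary = PathotypeSummary(
        n_total=n_total,
        n_graded=n_graded,
        counts={p.value: counts.get(p, 0) for p in Pathotype},
    )
    summary.graded_percent = round(100.0 * n_graded / n_total, 1)
    summary.failure_percent = round(100.0 - 100.0 * n_graded / n_total, 1)
    if n_graded > 0:
        graded_classes = [p for p in Pathotype if p is not Pathotype.UNGRADED]
        summary.proportions = {p.value: counts.get(p, 0) / n_graded for p in graded_classes}
        summary.percent = {p.value: round(100.0 * counts.get(p, 0) / n_graded) for p in graded_classes}
    return summary


def read_ihc(path) -> list[IHCScores]:
    """Read ihc.csv (columns sample_id, cd20, cd3, cd68_l, cd68_sl, cd138,
    aggregate_grade, gradeable)."""
    df = pd.read_csv(path)
    missing = [c for c in IHC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ihc file missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            IHCScores(
                sample_id=str(row.sample_id),
                cd20=int(row.cd20),
                cd3=int(row.cd3),
                cd68_lining=int(row.cd68_l),
                cd68_sublining=int(row.cd68_sl),
                cd138=int(row.cd138),
                aggregate_grade=int(row.aggregate_grade),
                gradeable=bool(row.gradeable),
            )
        )
    return out


def write_ihc(scores: Iterable[IHCScores], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "cd20": s.cd20,
            "cd3": s.cd3,
            "cd68_l": s.cd68_lining,
            "cd68_sl": s.cd68_sublining,
            "cd138": s.cd138,
            "aggregate_grade": s.aggregate_grade,
            "gradeable": s.gradeable,
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=IHC_COLUMNS).to_csv(path, index=False)
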