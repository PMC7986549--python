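"""Evaluation of certified cause-of-death data.

Computes the quantities used to judge a decision-support deployment:
cause-specific mortality fractions (CSMFs) with an explicit undetermined
entry, tool-usage and physician-agreement statistics, the reclassification
(confusion) matrix between algorithm top-1 and physician causes, the
fraction of ill-defined causes, aggregation of causes to broad categories,
and CSMF accuracy for synthetic-recovery experiments:

    CSMF accuracy = 1 - sum_j |true_j - est_j| / (2 * (1 - min_j true_j))

which is 1 for perfect population-level recovery and 0 when all estimated
mass sits on the rarest true cause.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .decision import PATHWAY_FULL_VA, CertificationOutcome
from .errors import ValidationError
from .schema import DEFAULT_ILL_DEFINED_CODES, UNDETERMINED, CauseList


@dataclass
class CSMFTable:
    """Normalized cause-fraction distribution, undetermined included."""

    fractions: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"CSMF fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValidationError("CSMF fractions must be non-negative")


@dataclass
class AgreementSummary:
    """Tool usage and physician-agreement statistics for a cohort."""

    n_total: int
    n_full_va: int
    usage_fraction: float
    used_tool_fraction: float       # among FULL_VA: physician cause in top-3
    agreement_top1_fraction: float  # among FULL_VA: physician cause == top-1
    n_disagreements: int            # FULL_VA deaths without top-1 agreement

    def rounded_percentages(self) -> dict[str, int]:
        """Integer percentages for human-readable reports."""
        return {
            "usage_pct": round(100 * self.usage_fraction),
            "used_tool_pct": round(100 * self.used_tool_fraction),
            "agreement_top1_pct": round(100 * self.agreement_top1_fraction),
        }


@dataclass
class ReclassificationMatrix:
    """Cross-tabulation of algorithm top-1 cause vs physician cause."""

    counts: pd.DataFrame        # rows: algorithm top-1, columns: physician
    row_percent: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def compute_csmf(
    assignments: Sequence[Optional[str]], causes: Optional[CauseList] = None
) -> CSMFTable:
    """Fraction of deaths per assigned cause; None counts as undetermined."""
    if not assignments:
        raise ValidationError("cannot compute a CSMF from zero deaths")
    counts: dict[str, int] = {}
    if causes is not None:
        for cause in causes.causes:
            counts[cause] = 0
        counts[UNDETERMINED] = 0
    for assignment in assignments:
        label = assignment if assignment is not None else UNDETERMINED
        counts[label] = counts.get(label, 0) + 1
    n = len(assignments)
    return CSMFTable(fractions={c: k / n for c, k in counts.items()}, n=n)


def agreement_stats(outcomes: Sequence[CertificationOutcome]) -> AgreementSummary:
    """Usage and agreement fractions over a cohort of certified deaths."""
    if not outcomes:
        raise ValidationError("cannot summarize zero outcomes")
    n_total = len(outcomes)
    full_va = [o for o in outcomes if o.pathway == PATHWAY_FULL_VA]
    n_full_va = len(full_va)
    n_used = sum(o.used_tool_diagnosis for o in full_va)
    n_top1 = sum(o.agreement_top1 for o in full_va)
    return AgreementSummary(
        n_total=n_total,
        n_full_va=n_full_va,
        usage_fraction=n_full_va / n_total,
        used_tool_fraction=n_used / n_full_va if n_full_va else 0.0,
        agreement_top1_fraction=n_top1 / n_full_va if n_full_va else 0.0,
        n_disagreements=n_full_va - n_top1,
    )


def reclassification_matrix(
    outcomes: Iterable[CertificationOutcome],
    restrict_to_disagreements: bool = False,
) -> ReclassificationMatrix:
    """Cross-tabulate algorithm top-1 against the physician's cause.

    Only FULL_VA outcomes with a determinate report are included; with
    ``restrict_to_disagreements`` only deaths whose physician cause differs
    from the algorithm's top-1 remain (the reclassification view).
    """
    pairs = [
        (o.report.top_cause, o.physician_cause)
        for o in outcomes
        if o.pathway == PATHWAY_FULL_VA
        and o.report is not None
        and not o.report.undetermined
        and (not restrict_to_disagreements or not o.agreement_top1)
    ]
    if not pairs:
        empty = pd.DataFrame(dtype=float)
        return ReclassificationMatrix(counts=empty, row_percent=empty)
    frame = pd.DataFrame(pairs, columns=["algorithm", "physician"])
    counts = pd.crosstab(frame["algorithm"], frame["physician"])
    row_percent = counts.div(counts.sum(axis=1), axis=0) * 100
    return ReclassificationMatrix(counts=counts, row_percent=row_percent)


def ill_defined_fraction(
    physician_causes: Sequence[str],
    codes: frozenset[str] = DEFAULT_ILL_DEFINED_CODES,
) -> float:
    """Fraction of certified causes that are ill-defined (garbage) codes.

    The engine's undetermined label counts as ill-defined alongside the
    configured ICD-10 codes (default R99 ill-defined, I46 cardiac arrest,
    R54 senility). Empty input gives 0.
    """
    if not physician_causes:
        return 0.0
    bad = set(codes) | {UNDETERMINED}
    return sum(c in bad for c in physician_causes) / len(physician_causes)


def map_cause_categories(
    cause: str,
    category_map: Mapping[str, str],
    residual_category: str = "other",
) -> str:
    """Aggregate a cause (including physician free entry) to its category."""
    return category_map.get(cause, residual_category)


def map_csmf_categories(
    table: CSMFTable,
    category_map: Mapping[str, str],
    residual_category: str = "other",
) -> CSMFTable:
    """Collapse a CSMF table onto aggregate categories (undetermined kept)."""
    collapsed: dict[str, float] = {}
    for cause, fraction in table.fractions.items():
        if cause == UNDETERMINED:
            category = UNDETERMINED
        else:
            category = map_cause_categories(cause, category_map, residual_category)
        collapsed[category] = collapsed.get(category, 0.0) + fraction
    return CSMFTable(fractions=collapsed, n=table.n)


def csmf_accuracy(true_csmf: CSMFTable, est_csmf: CSMFTable) -> float:
    """Population-level recovery of the cause distribution, in [0, 1].

    Cause universes are aligned by union with absent causes at 0. The single
    degenerate case (one cause holds all true mass) is defined as 1 when the
    estimate matches exactly and an error otherwise, since the normalizer
    2*(1 - min true) vanishes.
    """
    universe = sorted(set(true_csmf.fractions) | set(est_csmf.fractions))
    true = [true_csmf.fractions.get(c, 0.0) for c in universe]
    est = [est_csmf.fractions.get(c, 0.0) for c in universe]
    min_true = min(true) if true else 0.0
    l1 = sum(abs(a - b) for a, b in zip(true, est))
    if min_true >= 1.0 - 1e-12:
        if l1 <= 1e-12:
            return 1.0
        raise ValidationError(
            "CSMF accuracy undefined: true distribution is degenerate and the "
            "estimate differs"
        )
    return 1.0 - l1 / (2.0 * (1.0 - min_true))
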