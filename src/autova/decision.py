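"""Physician-facing decision support and certification routing.

Turns per-cause tariff scores into the report shown to the certifying
physician: demographically implausible causes are censored, causes must clear
an absolute score threshold and a rank-percentile threshold to qualify, the
top three qualifying causes are reported with likelihood categories
(possible, somewhat likely, likely, very likely) mapped from their rank
percentile, and an endorsed-symptom summary accompanies them. When no cause
qualifies the report is *undetermined* and the physician certifies unaided.

The default thresholds (min_score = 0.0, min_rank = 0.5) and likelihood bin
edges are artifact defaults, not published values; both are configuration.

The standard operating procedure routes each death before any scoring: a
physician who can certify from the medical records does so (RECORDS); failing
that, one confident in a diagnosis from the open narrative certifies without
the structured interview (NARRATIVE); only the remainder go through the full
structured VA with decision support (FULL_VA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigurationError, ValidationError
from .schema import SEXES, VARecord, age_in_days
from .tariff import CauseScores, TariffModel

PATHWAY_RECORDS = "RECORDS"
PATHWAY_NARRATIVE = "NARRATIVE"
PATHWAY_FULL_VA = "FULL_VA"
PATHWAYS = (PATHWAY_RECORDS, PATHWAY_NARRATIVE, PATHWAY_FULL_VA)

LIKELIHOOD_LABELS = ("possible", "somewhat likely", "likely", "very likely")


@dataclass(frozen=True)
class RestrictionRule:
    """Demographic plausibility rule for one cause.

    ``sexes`` lists the sexes the cause may be assigned to; the age interval
    is inclusive at both ends, in days, with ``None`` meaning unbounded.
    """

    cause: str
    sexes: tuple[str, ...] = SEXES
    min_age_days: Optional[float] = None
    max_age_days: Optional[float] = None

    def allows(self, record: VARecord) -> bool:
        if record.sex not in self.sexes:
            return False
        days = age_in_days(record.age_value, record.age_unit)
        if self.min_age_days is not None and days < self.min_age_days:
            return False
        if self.max_age_days is not None and days > self.max_age_days:
            return False
        return True


@dataclass
class RestrictionTable:
    rules: list[RestrictionRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rule in self.rules:
            if (
                rule.min_age_days is not None
                and rule.max_age_days is not None
                and rule.min_age_days > rule.max_age_days
            ):
                raise ConfigurationError(
                    f"restriction for {rule.cause!r} has an empty age interval"
                )

    def rules_for(self, cause: str) -> list[RestrictionRule]:
        return [r for r in self.rules if r.cause == cause]


@dataclass(frozen=True)
class Thresholds:
    """Qualification cutoffs: absolute score and rank percentile."""

    min_score: float = 0.0
    min_rank: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_rank <= 1.0:
            raise ConfigurationError("min_rank must lie in [0, 1]")


@dataclass(frozen=True)
class LikelihoodBins:
    """Rank-percentile bins mapping to likelihood categories.

    ``edges`` has one more element than ``labels``; bin k is
    (edges[k], edges[k+1]], except the bottom bin which is closed on the left
    so a cause qualifying exactly at the rank threshold still gets a label.
    """

    edges: tuple[float, ...] = (0.50, 0.65, 0.80, 0.95, 1.00)
    labels: tuple[str, ...] = LIKELIHOOD_LABELS

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.labels) + 1:
            raise ConfigurationError("need exactly one more edge than label")
        if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
            raise ConfigurationError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class RankedCause:
    cause: str
    score: float
    rank_percentile: float
    likelihood: str


@dataclass
class DecisionReport:
    """What the physician sees: endorsed symptoms and up to three causes."""

    death_id: str
    endorsed_symptoms: list[str]
    ranked_causes: list[RankedCause]  # best first, by rank percentile

    @property
    def undetermined(self) -> bool:
        return not self.ranked_causes

    @property
    def top_cause(self) -> Optional[str]:
        return self.ranked_causes[0].cause if self.ranked_causes else None

    @property
    def cause_ids(self) -> list[str]:
        return [rc.cause for rc in self.ranked_causes]


@dataclass
class CertificationOutcome:
    """One certified death: pathway, algorithm output, physician's cause."""

    death_id: str
    pathway: str
    report: Optional[DecisionReport]
    physician_cause: str
    used_tool_diagnosis: bool
    agreement_top1: bool


def apply_demographic_restrictions(
    scores: CauseScores, record: VARecord, table: RestrictionTable
) -> CauseScores:
    """Flag causes whose restriction rules exclude this record.

    Scores are retained for audit; excluded causes are only marked
    ineligible. A cause with no rule is unrestricted.
    """
    for cause in scores.scores:
        rules = table.rules_for(cause)
        if rules and not any(rule.allows(record) for rule in rules):
            scores.ineligible.add(cause)
    return scores


def qualify_causes(scores: CauseScores, th: Thresholds) -> list[tuple[str, float, float]]:
    """Eligible causes clearing both thresholds, best first.

    Ordered by rank percentile descending — raw tariff scores are not
    comparable across causes (each cause's tariff scale depends on how spread
    its symptom endorsement rates are), which is what the prevalence-equalized
    percentile rank corrects — with ties broken by score descending, then
    cause id, giving a deterministic order for audit. An empty list signals
    undetermined.
    """
    qualifying = [
        (cause, score, scores.ranks[cause])
        for cause, score in scores.scores.items()
        if cause not in scores.ineligible
        and score >= th.min_score
        and scores.ranks[cause] >= th.min_rank
    ]
    qualifying.sort(key=lambda item: (-item[2], -item[1], item[0]))
    return qualifying


def assign_likelihood(rank_percentile: float, bins: LikelihoodBins) -> str:
    """Map a qualifying cause's rank percentile to its likelihood category."""
    if rank_percentile < bins.edges[0]:
        raise ValidationError(
            f"rank percentile {rank_percentile} below the qualifying range "
            f"[{bins.edges[0]}, {bins.edges[-1]}]"
        )
    if rank_percentile == bins.edges[0]:
        return bins.labels[0]
    for k, label in enumerate(bins.labels):
        if rank_percentile <= bins.edges[k + 1]:
            return label
    return bins.labels[-1]


def build_decision_report(
    record: VARecord,
    model: TariffModel,
    thresholds: Thresholds = Thresholds(),
    bins: LikelihoodBins = LikelihoodBins(),
    restrictions: RestrictionTable = RestrictionTable(),
) -> DecisionReport:
    """Score a death and assemble the physician-facing report."""
    scores = model.score(record)
    scores = apply_demographic_restrictions(scores, record, restrictions)
    qualifying = qualify_causes(scores, thresholds)
    ranked = [
        RankedCause(
            cause=cause,
            score=score,
            rank_percentile=rank,
            likelihood=assign_likelihood(rank, bins),
        )
        for cause, score, rank in qualifying[:3]
    ]
    endorsed = [s for s in model.schema.symptoms if record.endorsements.get(s) == 1]
    return DecisionReport(
        death_id=record.death_id, endorsed_symptoms=endorsed, ranked_causes=ranked
    )


def route_certification(record: VARecord) -> str:
    """Choose the certification pathway for a death per the SOP.

    Medical records that suffice for certification short-circuit everything;
    otherwise a physician confident from the open narrative certifies without
    the structured interview; the rest get the full VA with decision support.
    """
    if record.medical_records_available and record.records_confident:
        return PATHWAY_RECORDS
    if record.narrative_confident:
        return PATHWAY_NARRATIVE
    return PATHWAY_FULL_VA


def record_certification(
    pathway: str,
    report: Optional[DecisionReport],
    physician_cause: str,
    death_id: Optional[str] = None,
) -> CertificationOutcome:
    """Combine the algorithm's report with the physician's certified cause."""
    if pathway not in PATHWAYS:
        raise ValidationError(f"unknown pathway {pathway!r}")
    if not physician_cause:
        raise ValidationError("physician cause must be non-empty")
    if pathway == PATHWAY_FULL_VA and report is None:
        raise ValidationError("FULL_VA outcomes require a decision report")
    if pathway != PATHWAY_FULL_VA and report is not None:
        raise ValidationError(f"pathway {pathway} must not carry a decision report")
    if report is not None:
        used = physician_cause in report.cause_ids
        agree = physician_cause == report.top_cause
        death_id = death_id or report.death_id
    else:
        used = False
        agree = False
        death_id = death_id or ""
    return CertificationOutcome(
        death_id=death_id,
        pathway=pathway,
        report=report,
        physician_cause=physician_cause,
        used_tool_diagnosis=used,
        agreement_top1=agree,
    )
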