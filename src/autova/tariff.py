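"""Tariff scoring engine.

The tariff method assigns each (symptom, cause) pair a real-valued *tariff*
measuring how distinctively that symptom's endorsement rate for the cause
departs from its rate across all causes:

    t[i, j] = (x[i, j] - median_j'(x[i, j'])) / max(IQR_j'(x[i, j']), eps)

where x[i, j] is the fraction of training deaths of cause j that endorsed
symptom i. Tariffs are rounded to a configurable granularity (default 0.5,
half away from zero) and optionally truncated to the K largest-magnitude
tariffs per cause. A death's score for cause j is the sum of tariffs of its
endorsed symptoms; missing responses contribute nothing.

Scores are placed on a comparable scale across causes by ranking them within
a prevalence-equalized reference: the training library is resampled with
replacement to the same number of deaths per cause, the pooled resample is
scored against every cause, and a death's percentile rank for cause j is its
mid-rank position among the pooled reference scores for j. Equalizing cause
prevalence in the reference makes ranks comparable across causes regardless
of how common each cause is in training.

PRNG contract: ``build_rank_reference`` uses a single
``numpy.random.default_rng(seed)`` generator; for each cause, in the tariff
matrix's cause order, it draws ``per_cause_n`` indices via
``rng.integers(0, n_cause, size=per_cause_n)`` into that cause's training
deaths in library order. An independent implementation replaying this mapping
reproduces the reference bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .schema import CauseList, SymptomSchema, VARecord

EPSILON_IQR = 0.001


@dataclass(frozen=True)
class TrainingDeath:
    death_id: str
    cause: str
    endorsements: Mapping[str, int]


@dataclass
class TrainingLibrary:
    """Gold-standard deaths with known causes, per questionnaire module."""

    module_id: str
    deaths: list[TrainingDeath]

    def by_cause(self) -> dict[str, list[TrainingDeath]]:
        grouped: dict[str, list[TrainingDeath]] = {}
        for death in self.deaths:
            grouped.setdefault(death.cause, []).append(death)
        return grouped


@dataclass(frozen=True)
class TariffOptions:
    """Constants of the tariff construction; all configurable.

    granularity: rounding step for tariffs (half away from zero); None or 0
        disables rounding.
    epsilon: floor for the across-cause IQR, preventing division by zero for
        symptoms endorsed at (nearly) identical rates everywhere.
    truncate_top_k: keep only the K largest-magnitude tariffs per cause,
        zeroing the rest; None disables truncation (useful for toy fixtures).
    """

    granularity: Optional[float] = 0.5
    epsilon: float = EPSILON_IQR
    truncate_top_k: Optional[int] = 40


@dataclass
class EndorsementMatrix:
    """x[i, j]: fraction of cause-j training deaths endorsing symptom i."""

    x: pd.DataFrame  # index: symptom ids, columns: cause ids

    @property
    def symptoms(self) -> list[str]:
        return list(self.x.index)

    @property
    def causes(self) -> list[str]:
        return list(self.x.columns)


@dataclass
class TariffMatrix:
    """t[i, j]: tariff of symptom i for cause j, after rounding/truncation."""

    t: pd.DataFrame
    options: TariffOptions = field(default_factory=TariffOptions)

    @property
    def symptoms(self) -> list[str]:
        return list(self.t.index)

    @property
    def causes(self) -> list[str]:
        return list(self.t.columns)


@dataclass
class CauseScores:
    """Per-cause tariff scores (and percentile ranks) for one death."""

    death_id: str
    scores: dict[str, float]
    ranks: dict[str, float] = field(default_factory=dict)
    ineligible: set[str] = field(default_factory=set)


@dataclass
class RankReference:
    """Sorted pooled reference scores per cause, from a seeded resample."""

    scores: dict[str, np.ndarray]  # cause -> ascending score array
    per_cause_n: int
    seed: int


def compute_endorsement_matrix(
    training: TrainingLibrary,
    causes: CauseList,
    schema: SymptomSchema,
) -> EndorsementMatrix:
    """Empirical endorsement fractions per (symptom, cause).

    Missing endorsements count as not endorsed. Every cause in the cause list
    must have at least one training death.
    """
    if not training.deaths:
        raise ValidationError("training library is empty")
    grouped = training.by_cause()
    for cause in causes.causes:
        if not grouped.get(cause):
            raise ConfigurationError(f"cause {cause!r} has no training deaths")
    x = pd.DataFrame(
        0.0, index=list(schema.symptoms), columns=list(causes.causes)
    )
    for cause in causes.causes:
        deaths = grouped[cause]
        counts = np.zeros(len(schema.symptoms))
        for death in deaths:
            for i, symptom in enumerate(schema.symptoms):
                if death.endorsements.get(symptom) == 1:
                    counts[i] += 1
        x[cause] = counts / len(deaths)
    return EndorsementMatrix(x=x)


def _round_half_away(values: np.ndarray, granularity: float) -> np.ndarray:
    scaled = values / granularity
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) * granularity


def compute_tariff_matrix(
    x: EndorsementMatrix, options: TariffOptions = TariffOptions()
) -> TariffMatrix:
    """Median/IQR-standardize each symptom row of the endorsement matrix.

    Quantiles use linear interpolation between order statistics. A symptom
    endorsed at the same rate by every cause gets tariff 0 for all causes.
    """
    values = x.x.to_numpy(dtype=float)
    medians = np.median(values, axis=1, keepdims=True)
    q25 = np.percentile(values, 25, axis=1, keepdims=True)
    q75 = np.percentile(values, 75, axis=1, keepdims=True)
    iqr = np.maximum(q75 - q25, options.epsilon)
    t = (values - medians) / iqr
    if options.granularity:
        t = _round_half_away(t, options.granularity)
    if options.truncate_top_k is not None and options.truncate_top_k < t.shape[0]:
        k = options.truncate_top_k
        for j in range(t.shape[1]):
            order = np.argsort(-np.abs(t[:, j]), kind="stable")
            t[order[k:], j] = 0.0
    return TariffMatrix(
        t=pd.DataFrame(t, index=x.x.index, columns=x.x.columns), options=options
    )


def _score_endorsements(
    endorsements: Mapping[str, Optional[int]], t: TariffMatrix
) -> np.ndarray:
    mask = np.fromiter(
        (endorsements.get(symptom) == 1 for symptom in t.symptoms),
        dtype=bool,
        count=len(t.symptoms),
    )
    return t.t.to_numpy(dtype=float)[mask].sum(axis=0)


def score_death(record: VARecord, t: TariffMatrix, module_id: str = "") -> CauseScores:
    """Sum the tariffs of the record's endorsed symptoms for every cause."""
    if module_id and record.module_id != module_id:
        raise ValidationError(
            f"record {record.death_id!r} is in module {record.module_id!r}, "
            f"matrix expects {module_id!r}"
        )
    scores = _score_endorsements(record.endorsements, t)
    return CauseScores(
        death_id=record.death_id,
        scores=dict(zip(t.causes, scores.tolist())),
    )


def build_rank_reference(
    training: TrainingLibrary,
    t: TariffMatrix,
    per_cause_n: int = 100,
    seed: int = 0,
) -> RankReference:
    """Resample the library to equal cause prevalence and score the pool.

    For each cause, in tariff cause order, ``per_cause_n`` of its training
    deaths are drawn with replacement; the pooled resample is then scored
    against every cause, giving each cause a sorted reference of length
    ``n_causes * per_cause_n``. Deterministic given (training, t, per_cause_n,
    seed) under the module's documented PRNG contract.
    """
    if per_cause_n < 1:
        raise ValidationError("per_cause_n must be >= 1")
    grouped = training.by_cause()
    rng = np.random.default_rng(seed)
    pooled_scores: list[np.ndarray] = []
    for cause in t.causes:
        deaths = grouped.get(cause)
        if not deaths:
            raise ConfigurationError(f"cause {cause!r} has no training deaths")
        indices = rng.integers(0, len(deaths), size=per_cause_n)
        for idx in indices:
            pooled_scores.append(_score_endorsements(deaths[idx].endorsements, t))
    pool = np.vstack(pooled_scores)  # (n_causes*per_cause_n, n_causes)
    references = {
        cause: np.sort(pool[:, j]) for j, cause in enumerate(t.causes)
    }
    return RankReference(scores=references, per_cause_n=per_cause_n, seed=seed)


def percentile_rank(score: float, cause: str, ref: RankReference) -> float:
    """Mid-rank percentile of a score within a cause's reference, in [0, 1]."""
    if cause not in ref.scores:
        raise ValidationError(f"cause {cause!r} not in rank reference")
    arr = ref.scores[cause]
    lo = int(np.searchsorted(arr, score, side="left"))
    hi = int(np.searchsorted(arr, score, side="right"))
    return (lo + 0.5 * (hi - lo)) / len(arr)


def rank_scores(scores: CauseScores, ref: RankReference) -> CauseScores:
    """Attach percentile ranks for every scored cause."""
    scores.ranks = {
        cause: percentile_rank(value, cause, ref)
        for cause, value in scores.scores.items()
    }
    return scores


@dataclass
class TariffModel:
    """A trained engine: schema, causes, matrices and rank reference."""

    schema: SymptomSchema
    causes: CauseList
    endorsement: EndorsementMatrix
    tariff: TariffMatrix
    reference: RankReference

    @classmethod
    def train(
        cls,
        training: TrainingLibrary,
        causes: CauseList,
        schema: SymptomSchema,
        options: TariffOptions = TariffOptions(),
        per_cause_n: int = 100,
        seed: int = 0,
    ) -> "TariffModel":
        x = compute_endorsement_matrix(training, causes, schema)
        t = compute_tariff_matrix(x, options)
        ref = build_rank_reference(training, t, per_cause_n=per_cause_n, seed=seed)
        return cls(schema=schema, causes=causes, endorsement=x, tariff=t, reference=ref)

    def score(self, record: VARecord) -> CauseScores:
        scores = score_death(record, self.tariff, module_id=self.schema.module_id)
        return rank_scores(scores, self.reference)

    def to_dict(self) -> dict:
        return {
            "module_id": self.schema.module_id,
            "symptoms": list(self.schema.symptoms),
            "causes": list(self.causes.causes),
            "ill_defined_codes": sorted(self.causes.ill_defined_codes),
            "category_map": dict(self.causes.category_map),
            "residual_category": self.causes.residual_category,
            "endorsement": self.endorsement.x.to_numpy().tolist(),
            "tariff": self.tariff.t.to_numpy().tolist(),
            "options": {
                "granularity": self.tariff.options.granularity,
                "epsilon": self.tariff.options.epsilon,
                "truncate_top_k": self.tariff.options.truncate_top_k,
            },
            "reference": {
                "per_cause_n": self.reference.per_cause_n,
                "seed": self.reference.seed,
                "scores": {c: arr.tolist() for c, arr in self.reference.scores.items()},
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TariffModel":
        schema = SymptomSchema(
            module_id=payload["module_id"], symptoms=tuple(payload["symptoms"])
        )
        causes = CauseList(
            causes=tuple(payload["causes"]),
            ill_defined_codes=frozenset(payload["ill_defined_codes"]),
            category_map=payload.get("category_map", {}),
            residual_category=payload.get("residual_category", "other"),
        )
        options = TariffOptions(**payload["options"])
        index = list(schema.symptoms)
        columns = list(causes.causes)
        x = EndorsementMatrix(
            x=pd.DataFrame(payload["endorsement"], index=index, columns=columns)
        )
        t = TariffMatrix(
            t=pd.DataFrame(payload["tariff"], index=index, columns=columns),
            options=options,
        )
        ref_payload = payload["reference"]
        ref = RankReference(
            scores={c: np.asarray(v, dtype=float) for c, v in ref_payload["scores"].items()},
            per_cause_n=ref_payload["per_cause_n"],
            seed=ref_payload["seed"],
        )
        return cls(schema=schema, causes=causes, endorsement=x, tariff=t, reference=ref)
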