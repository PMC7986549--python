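"""Synthetic training libraries, field cohorts and physician behaviour.

No gold-standard VA dataset ships with this package, so everything the
pipeline needs is generated: cause-conditional symptom-endorsement profiles,
training libraries drawn from them, field cohorts with known true causes and
medical-record availability, and a stochastic physician who accepts,
overrides or refines the algorithm's suggestions.

Each cause owns a small *signature* set of symptoms endorsed with probability
0.5 + 0.5*sharpness while every other symptom is endorsed at the background
rate 0.5*(1 - sharpness). ``sharpness=1`` gives perfectly separable causes
(signatures always endorsed, background never), ``sharpness=0`` makes every
symptom a coin flip. Signature sets are disjoint whenever the symptom budget
allows (n_symptoms >= n_causes * signature_size); otherwise overlapping
random subsets are drawn and a warning is logged.

Cohort defaults mirror the deployment this models: an adult-module population
(ages uniform on 20-90 years, 55% male), medical records available for 33.4%
of deaths, physicians certifying directly from records for 31% of those, and
a narrative-only certification for ~9.5% of the rest — leaving roughly 81% of
deaths to the full structured VA. Physician behaviour defaults accept the
top-1 cause 85% of the time (one of ranks 2-3 half the remaining time, when
present) and refine 5% of certified causes to a more specific free-entry
label.

All generators take an integer seed and are bit-reproducible: one
``numpy.random.default_rng(seed)`` generator per call, consumed in the
documented order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .decision import DecisionReport
from .errors import ValidationError
from .schema import MODULE_ADULT, SymptomSchema, VARecord
from .tariff import TrainingDeath, TrainingLibrary

logger = logging.getLogger("autova")

SIGNATURE_SIZE = 3
REFINED_SUFFIX = "::refined"


@dataclass(frozen=True)
class CauseProfile:
    """Per-symptom endorsement probabilities for one cause."""

    cause: str
    probabilities: tuple[float, ...]  # aligned with the generated schema order

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValidationError("endorsement probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PhysicianBehaviour:
    """Stochastic model of how a physician treats the algorithm's report.

    With probability ``p_accept_top1`` the top cause is certified; otherwise
    with ``p_accept_top23`` one of ranks 2-3 is chosen uniformly; otherwise
    (and always for undetermined reports, since some cause must go on the
    certificate) a cause is drawn from the override distribution. An accepted
    or overridden cause is replaced by a more specific free-entry refinement
    (e.g. a cancer site) with probability ``p_refine``.
    """

    p_accept_top1: float = 0.85
    p_accept_top23: float = 0.50
    p_refine: float = 0.05
    override: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_accept_top1", "p_accept_top23", "p_refine"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.override:
            total = sum(self.override.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.override.values()):
                raise ValidationError("override distribution must be a probability vector")


def uniform_override(causes: Sequence[str]) -> dict[str, float]:
    """Uniform override distribution over a cause list."""
    return {c: 1.0 / len(causes) for c in causes}


def symptom_schema_for(n_symptoms: int, module_id: str = MODULE_ADULT) -> SymptomSchema:
    """The symptom schema the generators emit: s01, s02, ..."""
    width = max(2, len(str(n_symptoms)))
    return SymptomSchema(
        module_id=module_id,
        symptoms=tuple(f"s{i:0{width}d}" for i in range(1, n_symptoms + 1)),
    )


def generate_cause_profiles(
    n_causes: int,
    n_symptoms: int,
    sharpness: float,
    seed: int,
    signature_size: int = SIGNATURE_SIZE,
) -> list[CauseProfile]:
    """Cause-conditional endorsement profiles with signature symptom sets."""
    if n_causes < 2:
        raise ValidationError("need at least two causes")
    if n_symptoms < n_causes:
        raise ValidationError("need at least as many symptoms as causes")
    if not 0.0 <= sharpness <= 1.0:
        raise ValidationError("sharpness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    signature_p = 0.5 + 0.5 * sharpness
    background_p = 0.5 * (1.0 - sharpness)
    if n_symptoms >= n_causes * signature_size:
        permuted = rng.permutation(n_symptoms)
        signatures = [
            permuted[j * signature_size : (j + 1) * signature_size]
            for j in range(n_causes)
        ]
    else:
        logger.warning(
            "symptom budget too small for disjoint signatures "
            "(%d symptoms < %d causes x %d); allowing overlap",
            n_symptoms,
            n_causes,
            signature_size,
        )
        signatures = [
            rng.choice(n_symptoms, size=min(signature_size, n_symptoms), replace=False)
            for _ in range(n_causes)
        ]
    profiles = []
    for j in range(n_causes):
        probabilities = np.full(n_symptoms, background_p)
        probabilities[signatures[j]] = signature_p
        profiles.append(
            CauseProfile(cause=f"cause_{j + 1:02d}", probabilities=tuple(probabilities))
        )
    return profiles


def generate_training_library(
    profiles: Sequence[CauseProfile],
    deaths_per_cause: int,
    seed: int,
    module_id: str = MODULE_ADULT,
) -> TrainingLibrary:
    """Draw a gold-standard library, one Bernoulli draw per symptom."""
    if deaths_per_cause < 1:
        raise ValidationError("deaths_per_cause must be >= 1")
    rng = np.random.default_rng(seed)
    n_symptoms = len(profiles[0].probabilities)
    schema = symptom_schema_for(n_symptoms, module_id)
    deaths: list[TrainingDeath] = []
    for profile in profiles:
        p = np.asarray(profile.probabilities)
        draws = rng.random((deaths_per_cause, n_symptoms)) < p
        for k in range(deaths_per_cause):
            deaths.append(
                TrainingDeath(
                    death_id=f"train-{profile.cause}-{k + 1:04d}",
                    cause=profile.cause,
                    endorsements=dict(zip(schema.symptoms, draws[k].astype(int).tolist())),
                )
            )
    return TrainingLibrary(module_id=module_id, deaths=deaths)


def generate_field_cohort(
    profiles: Sequence[CauseProfile],
    true_csmf: Mapping[str, float],
    n: int,
    p_records_available: float = 0.334,
    seed: int = 0,
    p_certify_from_records: float = 0.31,
    p_narrative_confident: float = 0.095,
    p_male: float = 0.55,
    age_range_years: tuple[float, float] = (20.0, 90.0),
) -> list[VARecord]:
    """Simulate a field cohort of out-of-facility deaths with known truth.

    True causes are drawn from ``true_csmf``; endorsements from the cause's
    profile; record availability, certify-from-records confidence, narrative
    confidence and sex are independent Bernoulli draws; ages are uniform on
    the adult range by default.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    causes = [p.cause for p in profiles]
    weights = np.array([true_csmf.get(c, 0.0) for c in causes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
        raise ValidationError("true_csmf must be a probability vector over the profiles")
    rng = np.random.default_rng(seed)
    n_symptoms = len(profiles[0].probabilities)
    schema = symptom_schema_for(n_symptoms)
    prob_matrix = np.asarray([p.probabilities for p in profiles])

    cause_idx = rng.choice(len(causes), size=n, p=weights)
    endorsement_draws = rng.random((n, n_symptoms)) < prob_matrix[cause_idx]
    ages = rng.uniform(age_range_years[0], age_range_years[1], size=n)
    sexes = np.where(rng.random(n) < p_male, "male", "female")
    records_available = rng.random(n) < p_records_available
    records_confident = records_available & (rng.random(n) < p_certify_from_records)
    narrative_confident = rng.random(n) < p_narrative_confident

    cohort = []
    for i in range(n):
        cohort.append(
            VARecord(
                death_id=f"field-{i + 1:05d}",
                age_value=round(float(ages[i]), 1),
                age_unit="years",
                sex=str(sexes[i]),
                endorsements=dict(
                    zip(schema.symptoms, endorsement_draws[i].astype(int).tolist())
                ),
                medical_records_available=bool(records_available[i]),
                records_confident=bool(records_confident[i]),
                narrative_confident=bool(narrative_confident[i]),
                respondent_is_family=True,
                true_cause=causes[cause_idx[i]],
            )
        )
    return cohort


def simulate_physician(
    report: DecisionReport,
    behaviour: PhysicianBehaviour,
    seed: Union[int, np.random.Generator],
) -> str:
    """Draw the cause a physician certifies given the algorithm's report.

    ``seed`` may be an integer or a live generator (so a cohort can share one
    stream). Undetermined reports always fall back to the override
    distribution: the certificate cannot be left blank.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not behaviour.override:
        raise ValidationError("behaviour needs an override distribution")
    override_causes = list(behaviour.override)
    override_p = np.array([behaviour.override[c] for c in override_causes])

    if report.undetermined:
        choice = str(rng.choice(override_causes, p=override_p))
    elif rng.random() < behaviour.p_accept_top1:
        choice = report.ranked_causes[0].cause
    elif len(report.ranked_causes) > 1 and rng.random() < behaviour.p_accept_top23:
        alternatives = [rc.cause for rc in report.ranked_causes[1:3]]
        choice = str(rng.choice(alternatives))
    else:
        choice = str(rng.choice(override_causes, p=override_p))
    if rng.random() < behaviour.p_refine:
        choice = choice + REFINED_SUFFIX
    return choice


@dataclass
class StudyResult:
    """Everything a simulated pilot produces, for evaluation."""

    model: "TariffModel"
    cohort: list[VARecord]
    reports: dict[str, DecisionReport]  # FULL_VA deaths only
    outcomes: list["CertificationOutcome"]


def simulate_study(
    n_causes: int = 10,
    n_symptoms: int = 40,
    sharpness: float = 0.8,
    deaths_per_cause: int = 200,
    cohort_n: int = 2000,
    true_csmf: Optional[Mapping[str, float]] = None,
    behaviour: Optional[PhysicianBehaviour] = None,
    seed: int = 0,
    **cohort_kwargs,
) -> StudyResult:
    """Run the whole pipeline on synthetic data: train, route, score, certify.

    Deaths routed to the RECORDS or NARRATIVE pathways are certified with
    their true cause (the physician had independent evidence); FULL_VA deaths
    get a decision report and a stochastic physician response. Sub-seeds for
    the profile, training, cohort, rank-reference and physician draws are
    derived from ``seed`` with a seeded generator, so one integer reproduces
    the study.
    """
    from .decision import (
        PATHWAY_FULL_VA,
        Thresholds,
        LikelihoodBins,
        RestrictionTable,
        build_decision_report,
        record_certification,
        route_certification,
    )
    from .schema import CauseList
    from .tariff import TariffModel

    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=5)
    profiles = generate_cause_profiles(n_causes, n_symptoms, sharpness, seed=int(seeds[0]))
    causes = CauseList(causes=tuple(p.cause for p in profiles))
    if true_csmf is None:
        true_csmf = uniform_override([p.cause for p in profiles])
    training = generate_training_library(profiles, deaths_per_cause, seed=int(seeds[1]))
    schema = symptom_schema_for(n_symptoms)
    model = TariffModel.train(training, causes, schema, seed=int(seeds[2]))
    cohort = generate_field_cohort(
        profiles, true_csmf, cohort_n, seed=int(seeds[3]), **cohort_kwargs
    )
    if behaviour is None:
        behaviour = PhysicianBehaviour(override=uniform_override(list(causes.causes)))
    physician_rng = np.random.default_rng(int(seeds[4]))

    thresholds = Thresholds()
    bins = LikelihoodBins()
    restrictions = RestrictionTable()
    reports: dict[str, DecisionReport] = {}
    outcomes = []
    for record in cohort:
        pathway = route_certification(record)
        if pathway == PATHWAY_FULL_VA:
            report = build_decision_report(record, model, thresholds, bins, restrictions)
            reports[record.death_id] = report
            physician_cause = simulate_physician(report, behaviour, physician_rng)
            outcomes.append(record_certification(pathway, report, physician_cause))
        else:
            outcomes.append(
                record_certification(
                    pathway, None, record.true_cause, death_id=record.death_id
                )
            )
    return StudyResult(model=model, cohort=cohort, reports=reports, outcomes=outcomes)
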