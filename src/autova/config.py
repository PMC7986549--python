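"""Configuration file loaders (YAML or JSON; YAML is a superset).

Everything the paper treats as fixed instrument content — the symptom list,
the cause list with its ill-defined codes and category aggregation, the
qualification thresholds, likelihood bins and demographic restrictions — is
configuration here.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import yaml

from .decision import LikelihoodBins, RestrictionRule, RestrictionTable, Thresholds
from .errors import SchemaError, ValidationError
from .schema import DEFAULT_ILL_DEFINED_CODES, CauseList, SymptomSchema, parse_bool
from .tariff import TariffOptions, TrainingDeath, TrainingLibrary


def _load(path: Union[str, Path]) -> dict:
    with open(path, encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return payload


def load_symptom_schema(path: Union[str, Path]) -> SymptomSchema:
    """schema.yaml: {module_id: adult, symptoms: [s01, s02, ...]}"""
    payload = _load(path)
    try:
        return SymptomSchema(
            module_id=payload["module_id"], symptoms=tuple(payload["symptoms"])
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing field {exc.args[0]!r}") from exc


def load_cause_list(path: Union[str, Path]) -> CauseList:
    """causes.yaml: cause ids plus ill-defined codes and a category map."""
    payload = _load(path)
    try:
        causes = tuple(payload["causes"])
    except KeyError as exc:
        raise SchemaError(f"{path}: missing field 'causes'") from exc
    return CauseList(
        causes=causes,
        ill_defined_codes=frozenset(
            payload.get("ill_defined_codes", sorted(DEFAULT_ILL_DEFINED_CODES))
        ),
        category_map=payload.get("category_map", {}),
        residual_category=payload.get("residual_category", "other"),
    )


def load_decision_config(
    path: Union[str, Path],
) -> tuple[Thresholds, LikelihoodBins, RestrictionTable, TariffOptions]:
    """decision.yaml: thresholds, likelihood bins, restrictions, tariff options."""
    payload = _load(path)
    thresholds = Thresholds(**payload.get("thresholds", {}))
    bins_payload = payload.get("likelihood_bins", {})
    bins = LikelihoodBins(
        edges=tuple(bins_payload.get("edges", LikelihoodBins().edges)),
        labels=tuple(bins_payload.get("labels", LikelihoodBins().labels)),
    )
    rules = [
        RestrictionRule(
            cause=rule["cause"],
            sexes=tuple(rule.get("sexes", ("male", "female"))),
            min_age_days=rule.get("min_age_days"),
            max_age_days=rule.get("max_age_days"),
        )
        for rule in payload.get("restrictions", [])
    ]
    options = TariffOptions(**payload.get("tariff_options", {}))
    return thresholds, bins, RestrictionTable(rules=rules), options


def load_training_csv(
    path: Union[str, Path], schema: SymptomSchema, module_id: str = ""
) -> TrainingLibrary:
    """Training CSV: death_id, cause, then one column per symptom id.

    Missing or blank endorsements load as not endorsed (binary library).
    """
    deaths: list[TrainingDeath] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        for column in ("death_id", "cause"):
            if column not in header:
                raise SchemaError(f"missing required column {column!r}")
        for row in reader:
            endorsements = {}
            for symptom in schema.symptoms:
                cell = (row.get(symptom) or "").strip()
                endorsements[symptom] = int(parse_bool(cell, default=False)) if cell else 0
            cause = (row.get("cause") or "").strip()
            if not cause:
                raise ValidationError(f"training death {row.get('death_id')!r} has no cause")
            deaths.append(
                TrainingDeath(
                    death_id=(row.get("death_id") or "").strip(),
                    cause=cause,
                    endorsements=endorsements,
                )
            )
    return TrainingLibrary(module_id=module_id or schema.module_id, deaths=deaths)
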