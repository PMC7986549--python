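"""Independent brute-force oracles for the tariff pipeline.

Everything here is written from the definitions with plain Python loops and
manual order-statistic interpolation — no numpy quantiles, no shared code
with the implementation — so agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np


def quantile_linear(values: list[float], q: float) -> float:
    """Quantile with linear interpolation between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    frac = h - lo
    if lo + 1 < len(v):
        return v[lo] + frac * (v[lo + 1] - v[lo])
    return v[lo]


def round_half_away(value: float, granularity: float) -> float:
    scaled = value / granularity
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) * granularity


def brute_endorsement(deaths, symptoms, causes) -> dict[str, dict[str, float]]:
    """x[symptom][cause] by explicit counting. deaths: (cause, {symptom: 0/1})."""
    x: dict[str, dict[str, float]] = {s: {} for s in symptoms}
    for cause in causes:
        members = [e for c, e in deaths if c == cause]
        for symptom in symptoms:
            endorsed = sum(1 for e in members if e.get(symptom) == 1)
            x[symptom][cause] = endorsed / len(members)
    return x


def brute_tariff(
    x: dict[str, dict[str, float]],
    causes,
    epsilon: float = 0.001,
    granularity: float | None = 0.5,
) -> dict[str, dict[str, float]]:
    """Median/IQR standardization of each symptom row, by the definition."""
    t: dict[str, dict[str, float]] = {}
    for symptom, row in x.items():
        rates = [row[c] for c in causes]
        med = quantile_linear(rates, 0.5)
        iqr = max(quantile_linear(rates, 0.75) - quantile_linear(rates, 0.25), epsilon)
        t[symptom] = {}
        for cause in causes:
            raw = (row[cause] - med) / iqr
            t[symptom][cause] = (
                round_half_away(raw, granularity) if granularity else raw
            )
    return t


def brute_score(endorsements, t: dict[str, dict[str, float]], causes) -> dict[str, float]:
    """Double-loop sum of tariffs over endorsed symptoms."""
    scores = {c: 0.0 for c in causes}
    for symptom, row in t.items():
        if endorsements.get(symptom) == 1:
            for cause in causes:
                scores[cause] += row[cause]
    return scores


def brute_rank_reference(deaths_by_cause, t, causes, per_cause_n, seed):
    """Replay the documented PRNG contract with brute-force scoring.

    One numpy.random.default_rng(seed); per cause in the given order, draw
    per_cause_n indices via rng.integers(0, n_cause, size=per_cause_n); pool
    the sampled deaths; reference for cause j = sorted pooled scores against j.
    """
    rng = np.random.default_rng(seed)
    pooled = []
    for cause in causes:
        members = deaths_by_cause[cause]
        for idx in rng.integers(0, len(members), size=per_cause_n):
            pooled.append(members[int(idx)])
    reference = {}
    for cause in causes:
        scores = sorted(brute_score(e, t, causes)[cause] for e in pooled)
        reference[cause] = scores
    return reference


def brute_percentile_rank(score: float, reference: list[float]) -> float:
    below = sum(1 for r in reference if r < score)
    equal = sum(1 for r in reference if r == score)
    return (below + 0.5 * equal) / len(reference)
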