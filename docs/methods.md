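# Methods

## The problem being modelled

Out-of-facility deaths are certified by a physician from a family interview,
sometimes with medical records, often without. The package models a
decision-support deployment: a structured verbal-autopsy (VA) interview
produces binary symptom endorsements; a tariff classifier turns them into a
short ranked cause list with likelihood labels; a standard operating
procedure (SOP) decides which deaths need the tool at all; and the certified
causes are evaluated at the population level.

## Tariff model

Let `x_ij` be the fraction of training deaths of cause `j` that endorsed
symptom `i` (missing endorsements count as "no": the instrument is a
checkbox). The tariff is

```
t_ij = (x_ij − median_j'(x_ij')) / max(IQR_j'(x_ij'), ε)
```

with quantiles computed by linear interpolation between order statistics,
`ε = 0.001` guarding symptoms endorsed at (near-)identical rates everywhere.
Tariffs are rounded to a granularity of 0.5 (half away from zero) and can be
truncated to the `K = 40` largest-magnitude tariffs per cause; both are
configuration (`TariffOptions`), and truncation is typically disabled for
toy fixtures. A death's score for cause `j` is the sum of `t_ij` over
endorsed symptoms — additive by construction, zero for an empty endorsement
set. Bootstrap significance-zeroing of individual tariffs is deliberately
not implemented; the option surface leaves room for it, but determinism at
desk scale was preferred.

### Rank reference

Raw tariff scores are not comparable across causes: a cause whose
endorsement-rate row has a small across-cause IQR gets a systematically
inflated tariff scale. Scores are therefore converted to percentile ranks
against a prevalence-equalized reference: the training library is resampled
with replacement to `per_cause_n = 100` deaths per cause, the pooled
resample is scored against every cause, and a death's rank for cause `j` is
the mid-rank percentile of its score among the pooled scores-against-`j`
(length `n_causes × per_cause_n`). Equal prevalence in the pool means a rank
of 0.5 has the same meaning for a rare and a common training cause.

PRNG contract: one `numpy.random.default_rng(seed)` generator; for each
cause in tariff-matrix column order, indices are drawn as
`rng.integers(0, n_cause, size=per_cause_n)` into that cause's training
deaths in library order. Tests replay this contract with an independent
brute-force scorer.

### Qualification, ordering and likelihood

A cause qualifies if it survives demographic restrictions (sex and age
interval rules; restrict-then-threshold order), scores at least `min_score`
(default 0.0) and ranks at least `min_rank` (default 0.5). These defaults
are artifact defaults — the thresholds used by deployed tools are not
public — and are fully configurable. Qualifying causes are ordered by rank
percentile descending (ties: score descending, then cause id): ordering by
raw score re-introduces the cross-cause scale problem the rank step exists
to fix, and measurably biases top-1 assignments toward small-IQR causes.
The top three are reported; none qualifying means an undetermined report.

Likelihood labels partition the qualifying rank range: [0.50, 0.65]
possible, (0.65, 0.80] somewhat likely, (0.80, 0.95] likely, (0.95, 1.00]
very likely. The bottom bin is closed on the left so a cause qualifying
exactly at `min_rank` still receives a label. The category names are the
standard four; the cut-points are configuration, chosen to split the
qualifying range evenly with a narrow top bin.

## SOP routing

Each death takes exactly one pathway, checked in order: **RECORDS** if
medical records are available *and* suffice for certification (availability
alone is not enough — in practice the tool is still used for most deaths
with records); **NARRATIVE** if the physician is confident from the open
narrative alone (the narrative is asked first, matching clinical practice);
otherwise **FULL_VA**, the structured interview with decision support. Only
FULL_VA deaths carry a decision report, and "used the tool's diagnosis" is
operationalized as the physician's cause appearing anywhere in the top
three, with top-1 agreement reported separately, since the two readings of
"used the diagnosis" cannot be distinguished after the fact.

## Evaluation

CSMF tables are plain empirical fractions with undetermined as its own
category, so they always normalize. Agreement summaries report usage
(FULL_VA share), tool-diagnosis use and top-1 agreement among FULL_VA
deaths, with human-readable values rounded to integer percentages and exact
fractions kept alongside. The reclassification matrix cross-tabulates
algorithm top-1 against physician cause over determinate FULL_VA outcomes,
optionally restricted to disagreements. The ill-defined fraction counts
{R99, I46, R54} plus the undetermined label. External cause-fraction tables
can be aggregated through the same category map for side-by-side
comparison; such sources are generally not strictly comparable with a VA
cohort and reports say so. CSMF accuracy is
`1 − Σ_j |true_j − est_j| / (2(1 − min_j true_j))` over the union of cause
universes; the degenerate single-cause truth is defined as 1 only for an
exact match.

## Synthetic data

The generators emulate the structure of a physician-VA deployment, not any
particular dataset:

- **Profiles.** Each cause gets a 3-symptom signature endorsed with
  probability `0.5 + 0.5·sharpness`; all other symptoms are background at
  `0.5·(1 − sharpness)`. Signatures are disjoint whenever
  `n_symptoms ≥ 3·n_causes` (seeded permutation), otherwise random subsets
  with a logged overlap warning. `sharpness = 1` is perfectly separable;
  `sharpness = 0` is pure noise.
- **Cohort.** Adult-module deaths, ages uniform on 20–90 years, 55% male.
  Medical records available with probability 0.334; physicians certify from
  records for 31% of those; the narrative suffices for 9.5% of the rest —
  leaving ≈81% of deaths to the full VA, the usage level reported for the
  deployment this emulates.
- **Physician.** Accepts the top-ranked cause with probability 0.85 (the
  reported tool-diagnosis use), one of ranks 2–3 with probability 0.50 when
  rejecting the top cause, otherwise draws from an override distribution
  (always, for undetermined reports — something must go on the
  certificate), and refines 5% of certified causes to a more specific
  free-entry label (modelled on cancer-site refinement), which counts as
  disagreement.

All generators are bit-reproducible from one integer seed;
`simulate_study` derives sub-seeds for profiles, training, reference,
cohort and physician draws from a single seeded generator.

What passing synthetic tests does **not** show: real symptom profiles are
correlated within a death, cause-conditional rates are not two-valued,
physicians are not exchangeable Bernoulli machines, and real cause lists
have strong demographic structure. Recovery results here certify the
pipeline's correctness and calibration behaviour, not field accuracy.

## Numerical and design choices

- Age bands are half-open — [0, 28) days, [28 days, 12 years), [12 years,
  ∞) — making the inclusive labels "0–27 days" and "28 days to 11 years"
  exhaustive and disjoint; years convert at 365.25 days/year, which decides
  the neonate/child boundary for ages reported only in years.
- Dirty field rows (unparseable age, unknown sex) are skipped with a
  machine-readable row report instead of aborting the batch; duplicate
  death ids and missing required columns abort, since they indicate a
  broken export rather than a bad row.
- Rounding is half away from zero at the configured granularity;
  tie-breaks everywhere are deterministic (documented sort keys) so reports
  are auditable.
- Problem sizes in the test and acceptance runs (10 causes × 40 symptoms,
  200 training deaths/cause, cohorts of 1,000–2,000, 10,000 physician
  draws) were chosen as the smallest sizes at which binomial noise is well
  below the effects being checked.

## Known limitations

- No free-text narrative processing; the narrative enters only as a
  routing flag.
- No chance-corrected concordance or uncertainty intervals on CSMFs.
- The cause list, symptom schema, restriction table and likelihood
  cut-points ship as configuration with small defaults; they are not a
  validated clinical instrument.
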