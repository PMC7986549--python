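"""Decision reports, threshold qualification and SOP routing."""

import pytest
from hypothesis import given, settings, strategies as st

from autova import (
    CauseScores,
    LikelihoodBins,
    RestrictionRule,
    RestrictionTable,
    Thresholds,
    VARecord,
    ValidationError,
    apply_demographic_restrictions,
    assign_likelihood,
    build_decision_report,
    qualify_causes,
    record_certification,
    route_certification,
)
from autova.decision import PATHWAY_FULL_VA, PATHWAY_NARRATIVE, PATHWAY_RECORDS, DecisionReport, RankedCause


def make_record(**overrides) -> VARecord:
    fields = dict(
        death_id="d1",
        age_value=40,
        age_unit="years",
        sex="male",
        endorsements={},
        medical_records_available=False,
    )
    fields.update(overrides)
    return VARecord(**fields)


def make_scores(scores, ranks, ineligible=()):
    return CauseScores(
        death_id="d1", scores=scores, ranks=ranks, ineligible=set(ineligible)
    )


class TestRestrictions:
    def test_empty_table_changes_nothing(self):
        scores = make_scores({"a": 1.0}, {"a": 0.9})
        out = apply_demographic_restrictions(scores, make_record(), RestrictionTable())
        assert out.ineligible == set()

    def test_sex_restriction_excludes(self):
        table = RestrictionTable(rules=[RestrictionRule(cause="a", sexes=("female",))])
        scores = make_scores({"a": 1.0, "b": 1.0}, {"a": 0.9, "b": 0.9})
        out = apply_demographic_restrictions(scores, make_record(sex="male"), table)
        assert out.ineligible == {"a"}
        assert out.scores["a"] == 1.0  # retained for audit

    def test_age_interval_rule_matches_hand_evaluation(self):
        # neonatal-only cause: first 28 days of life
        table = RestrictionTable(
            rules=[RestrictionRule(cause="a", min_age_days=0, max_age_days=27)]
        )
        cases = [
            (make_record(age_value=10, age_unit="days"), set()),
            (make_record(age_value=27, age_unit="days"), set()),
            (make_record(age_value=28, age_unit="days"), {"a"}),
            (make_record(age_value=40, age_unit="years"), {"a"}),
        ]
        for record, expected in cases:
            scores = make_scores({"a": 1.0}, {"a": 0.9})
            assert apply_demographic_restrictions(scores, record, table).ineligible == expected


class TestQualifyCauses:
    def test_no_cause_meets_thresholds_is_empty(self):
        scores = make_scores({"a": -1.0, "b": 2.0}, {"a": 0.9, "b": 0.3})
        assert qualify_causes(scores, Thresholds(min_score=0.0, min_rank=0.5)) == []

    def test_all_meet_thresholds_sorted_by_rank(self):
        scores = make_scores({"a": 1.0, "b": 3.0, "c": 2.0}, {"a": 0.6, "b": 0.7, "c": 0.8})
        result = qualify_causes(scores, Thresholds())
        assert [c for c, _, _ in result] == ["c", "b", "a"]

    def test_rank_ties_break_by_score_then_lexicographic(self):
        scores = make_scores(
            {"b": 2.0, "a": 2.0, "c": 1.0, "d": 3.0}, {"b": 0.7, "a": 0.7, "c": 0.7, "d": 0.9}
        )
        result = qualify_causes(scores, Thresholds())
        assert [c for c, _, _ in result] == ["d", "a", "b", "c"]

    def test_ineligible_causes_never_qualify(self):
        scores = make_scores({"a": 5.0, "b": 1.0}, {"a": 0.99, "b": 0.8}, ineligible={"a"})
        assert [c for c, _, _ in qualify_causes(scores, Thresholds())] == ["b"]

    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d", "e"]),
            st.tuples(
                st.floats(-5, 5, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=1,
            max_size=5,
        ),
        st.floats(-5, 5, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 2, allow_nan=False),
        st.floats(0, 0.5, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_abstention(self, table, min_score, min_rank, ds, dr):
        """Raising either threshold never increases the qualifying set."""
        scores = make_scores(
            {c: sv for c, (sv, _) in table.items()},
            {c: rv for c, (_, rv) in table.items()},
        )
        loose = qualify_causes(scores, Thresholds(min_score=min_score, min_rank=min_rank))
        strict = qualify_causes(
            scores,
            Thresholds(min_score=min_score + ds, min_rank=min(1.0, min_rank + dr)),
        )
        assert len(strict) <= len(loose)
        assert {c for c, _, _ in strict} <= {c for c, _, _ in loose}


class TestAssignLikelihood:
    def test_top_of_range_is_very_likely(self):
        assert assign_likelihood(1.0, LikelihoodBins()) == "very likely"

    def test_bottom_of_range_is_possible(self):
        assert assign_likelihood(0.5, LikelihoodBins()) == "possible"
        assert assign_likelihood(0.51, LikelihoodBins()) == "possible"

    def test_default_bins_lookup(self):
        assert assign_likelihood(0.85, LikelihoodBins()) == "likely"
        assert assign_likelihood(0.70, LikelihoodBins()) == "somewhat likely"
        assert assign_likelihood(0.96, LikelihoodBins()) == "very likely"

    def test_below_qualifying_range_is_a_contract_violation(self):
        with pytest.raises(ValidationError):
            assign_likelihood(0.4, LikelihoodBins())

    @given(st.floats(0.5, 1.0, allow_nan=False), st.floats(0.5, 1.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_rank(self, a, b):
        bins = LikelihoodBins()
        lo, hi = sorted((a, b))
        order = {label: k for k, label in enumerate(bins.labels)}
        assert order[assign_likelihood(lo, bins)] <= order[assign_likelihood(hi, bins)]


class TestBuildDecisionReport:
    def test_zero_endorsements_with_positive_min_score_is_undetermined(self, tiny_model):
        report = build_decision_report(
            make_record(), tiny_model, Thresholds(min_score=0.5, min_rank=0.0)
        )
        assert report.undetermined
        assert report.endorsed_symptoms == []
        assert report.ranked_causes == []

    def test_composition_matches_component_oracles(self, tiny_model):
        record = make_record(endorsements={"s01": 1, "s02": 1, "s05": 1})
        thresholds, bins = Thresholds(), LikelihoodBins()
        report = build_decision_report(record, tiny_model, thresholds, bins)
        scores = tiny_model.score(record)
        expected = qualify_causes(scores, thresholds)[:3]
        assert [rc.cause for rc in report.ranked_causes] == [c for c, _, _ in expected]
        for rc, (cause, score, rank) in zip(report.ranked_causes, expected):
            assert rc.score == pytest.approx(score)
            assert rc.rank_percentile == pytest.approx(rank)
            assert rc.likelihood == assign_likelihood(rank, bins)
        assert report.endorsed_symptoms == ["s01", "s02", "s05"]

    def test_at_most_three_causes_reported(self, tiny_model):
        # endorse every symptom: many causes score high
        record = make_record(
            endorsements={s: 1 for s in tiny_model.schema.symptoms}
        )
        report = build_decision_report(
            record, tiny_model, Thresholds(min_score=-100, min_rank=0.0),
            LikelihoodBins(edges=(0.0, 0.25, 0.5, 0.75, 1.0)),
        )
        scores = tiny_model.score(record)
        n_qualifying = len(qualify_causes(scores, Thresholds(min_score=-100, min_rank=0.0)))
        assert n_qualifying > 3
        assert len(report.ranked_causes) == 3


class TestRouting:
    @pytest.mark.parametrize(
        "records_avail,records_conf,narrative_conf,expected",
        [
            (True, True, False, PATHWAY_RECORDS),
            (True, True, True, PATHWAY_RECORDS),
            (False, False, True, PATHWAY_NARRATIVE),
            (True, False, True, PATHWAY_NARRATIVE),
            (False, False, False, PATHWAY_FULL_VA),
            (True, False, False, PATHWAY_FULL_VA),
        ],
    )
    def test_sop_branches(self, records_avail, records_conf, narrative_conf, expected):
        record = make_record(
            medical_records_available=records_avail,
            records_confident=records_conf,
            narrative_confident=narrative_conf,
        )
        assert route_certification(record) == expected

    def test_pathways_partition_a_cohort(self):
        import itertools

        cohort = [
            make_record(
                death_id=f"d{k}",
                medical_records_available=a,
                records_confident=b,
                narrative_confident=c,
            )
            for k, (a, b, c) in enumerate(itertools.product([False, True], repeat=3))
        ]
        pathways = [route_certification(r) for r in cohort]
        counts = {p: pathways.count(p) for p in set(pathways)}
        assert sum(counts.values()) == len(cohort)
        assert set(counts) <= {PATHWAY_RECORDS, PATHWAY_NARRATIVE, PATHWAY_FULL_VA}


def make_report(causes, death_id="d1"):
    return DecisionReport(
        death_id=death_id,
        endorsed_symptoms=["s01"],
        ranked_causes=[
            RankedCause(cause=c, score=3.0 - k, rank_percentile=0.9 - 0.1 * k,
                        likelihood="likely")
            for k, c in enumerate(causes)
        ],
    )


class TestRecordCertification:
    def test_physician_selects_top_cause(self):
        outcome = record_certification(PATHWAY_FULL_VA, make_report(["a", "b"]), "a")
        assert outcome.used_tool_diagnosis and outcome.agreement_top1

    def test_physician_selects_second_cause(self):
        outcome = record_certification(PATHWAY_FULL_VA, make_report(["a", "b"]), "b")
        assert outcome.used_tool_diagnosis and not outcome.agreement_top1

    def test_free_entry_refinement_counts_as_outside_tool(self):
        outcome = record_certification(
            PATHWAY_FULL_VA, make_report(["other cancers", "b"]), "nasopharyngeal cancer"
        )
        assert not outcome.used_tool_diagnosis and not outcome.agreement_top1

    def test_undetermined_report_never_counts_as_tool_use(self):
        outcome = record_certification(PATHWAY_FULL_VA, make_report([]), "a")
        assert not outcome.used_tool_diagnosis and not outcome.agreement_top1
        assert outcome.physician_cause == "a"

    def test_missing_physician_cause_errors(self):
        with pytest.raises(ValidationError):
            record_certification(PATHWAY_FULL_VA, make_report(["a"]), "")

    def test_report_required_exactly_on_full_va(self):
        with pytest.raises(ValidationError):
            record_certification(PATHWAY_RECORDS, make_report(["a"]), "a")
        with pytest.raises(ValidationError):
            record_certification(PATHWAY_FULL_VA, None, "a")
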