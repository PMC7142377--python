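import pytest
from hypothesis import given, strategies as st

from fnast8 import core
from fnast8.core import (
    ANY_TREMORS,
    BINARY_ITEMS,
    ITEM_DEFINITIONS,
    SIMPLIFIED_ITEMS,
    AssessmentRecord,
    MissingAnalysisDayError,
    SchemaError,
    ScoreCategory,
    TreatmentRule,
    binarize,
    categorize,
    extract_analysis_row,
    first_treatment_day,
    score_original,
    score_simplified,
)

# weights of every level, per item, as printed on the original instrument
PUBLISHED_WEIGHTS = {
    "high_pitched_crying": [2, 3],
    "sleeps_after_feeding": [1, 2, 3],
    "moro_reflex": [2, 3],
    "tremors_disturbed": [1, 2],
    "tremors_undisturbed": [3, 4],
    "increased_muscle_tone": [2],
    "excoriation": [1],
    "myoclonic_jerks": [3],
    "generalized_convulsions": [5],
    "sweating": [1],
    "body_temperature": [1, 2],
    "yawning": [1],
    "mottling": [1],
    "nasal_stuffiness": [1],
    "sneezing": [1],
    "nasal_flaring": [2],
    "respiratory_rate": [1, 2],
    "excessive_sucking": [1],
    "poor_feeding": [2],
    "vomiting": [2, 3],
    "stools": [2, 3],
}


def record(grades, **kw):
    defaults = dict(neonate_id="n", cohort_id="c", day_of_life=1, assessment_index=1)
    defaults.update(kw)
    return AssessmentRecord(grades=grades, **defaults)


class TestItemDefinitions:
    def test_reproduces_published_instrument(self):
        assert set(ITEM_DEFINITIONS) == set(PUBLISHED_WEIGHTS)
        assert len(ITEM_DEFINITIONS) == 21
        for item_id, weights in PUBLISHED_WEIGHTS.items():
            got = [lv.weight for lv in ITEM_DEFINITIONS[item_id].levels]
            assert got == weights, item_id

    def test_specific_weights(self):
        assert ITEM_DEFINITIONS["generalized_convulsions"].levels[0].weight == 5
        assert ITEM_DEFINITIONS["sleeps_after_feeding"].weight_of("lt_1h") == 3
        assert ITEM_DEFINITIONS["tremors_undisturbed"].weight_of("mild") == 3

    def test_weights_strictly_increase(self):
        for d in ITEM_DEFINITIONS.values():
            weights = [lv.weight for lv in d.levels]
            assert all(b > a for a, b in zip(weights, weights[1:]))
            assert all(1 <= w <= 5 for w in weights)

    def test_binary_groups_are_one_to_one(self):
        groups = [d.binary_group for d in ITEM_DEFINITIONS.values()]
        assert len(set(groups)) == 21
        assert set(groups) == set(BINARY_ITEMS)

    def test_invalid_definition_rejected(self):
        with pytest.raises(ValueError):
            core.ItemDefinition(
                "x", "x", (core.GradeLevel("a", 2), core.GradeLevel("b", 1)), "x"
            )


class TestScoreOriginal:
    def test_empty_assessment_scores_zero(self):
        assert score_original(record({})) == 0

    def test_published_example(self):
        rec = record(
            {
                "high_pitched_crying": "continuous",
                "sleeps_after_feeding": "lt_1h",
                "moro_reflex": "markedly_hyperactive",
            }
        )
        assert score_original(rec) == 9  # 3 + 3 + 3

    def test_maximum_possible_score(self):
        # independent oracle: sum the per-item maximum printed weights
        expected = sum(max(ws) for ws in PUBLISHED_WEIGHTS.values())
        assert expected == 46
        rec = record(
            {i: d.levels[-1].label for i, d in ITEM_DEFINITIONS.items()}
        )
        assert score_original(rec) == 46

    def test_unknown_item_named(self):
        with pytest.raises(SchemaError, match="bogus_item"):
            score_original(record({"bogus_item": "present"}))

    def test_unknown_grade_named(self):
        with pytest.raises(SchemaError, match="severe.*sweating|sweating"):
            score_original(record({"sweating": "severe"}))

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ITEM_DEFINITIONS)),
            st.integers(0, 3),
            max_size=21,
        )
    )
    def test_additivity(self, picks):
        grades = {
            item: ITEM_DEFINITIONS[item].levels[
                lvl % len(ITEM_DEFINITIONS[item].levels)
            ].label
            for item, lvl in picks.items()
        }
        total = score_original(record(grades))
        parts = sum(score_original(record({i: g})) for i, g in grades.items())
        assert total == parts


class TestBinarize:
    def test_any_level_codes_the_sign(self):
        flags = binarize(record({"moro_reflex": "markedly_hyperactive"})).flags
        assert flags["hyperactive_moro"]

    def test_watery_stools(self):
        flags = binarize(record({"stools": "watery"})).flags
        assert flags["loose_watery_stools"]

    def test_projectile_vomiting_maps_to_regurgitation(self):
        flags = binarize(record({"vomiting": "projectile"})).flags
        assert flags["regurgitation"]

    def test_either_temperature_level(self):
        for lvl in ("c_37_2_to_38_3", "ge_38_4"):
            assert binarize(record({"body_temperature": lvl})).flags["temp_ge_37_2"]

    def test_empty_assessment_all_absent(self):
        b = binarize(record({}))
        assert not any(b.flags.values())
        assert len(b.flags) == 21
        assert b.original_score == 0

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ITEM_DEFINITIONS)), st.integers(0, 3), max_size=21
        ),
        st.sampled_from(sorted(ITEM_DEFINITIONS)),
    )
    def test_adding_a_grade_is_monotone(self, picks, extra):
        grades = {
            item: ITEM_DEFINITIONS[item].levels[
                lvl % len(ITEM_DEFINITIONS[item].levels)
            ].label
            for item, lvl in picks.items()
        }
        bigger = dict(grades)
        bigger.setdefault(extra, ITEM_DEFINITIONS[extra].levels[0].label)
        assert score_original(record(bigger)) >= score_original(record(grades))
        assert score_simplified(binarize(record(bigger))) >= score_simplified(
            binarize(record(grades))
        )


class TestScoreSimplified:
    def test_all_eight_present(self):
        flags = {i: True for i in BINARY_ITEMS}
        assert core.simplified_score_from_flags(flags) == 8

    def test_none_present(self):
        assert core.simplified_score_from_flags({}) == 0

    def test_crying_not_on_simplified_scale(self):
        rec = record(
            {
                "tremors_undisturbed": "mild",
                "increased_muscle_tone": "present",
                "high_pitched_crying": "excessive",
            }
        )
        assert score_simplified(binarize(rec)) == 2

    def test_either_tremor_counts_once(self):
        both = core.simplified_score_from_flags(
            {"tremors_disturbed": True, "tremors_undisturbed": True}
        )
        one = core.simplified_score_from_flags({"tremors_disturbed": True})
        assert both == one == 1

    def test_simplified_items_list(self):
        assert len(SIMPLIFIED_ITEMS) == 8
        assert ANY_TREMORS in SIMPLIFIED_ITEMS


class TestCategorize:
    @pytest.mark.parametrize(
        "score,cutpoints,expected",
        [
            (7, (8, 12), ScoreCategory.LOW),
            (8, (8, 12), ScoreCategory.MEDIUM),
            (11, (8, 12), ScoreCategory.MEDIUM),
            (12, (8, 12), ScoreCategory.HIGH),
            (4, (4, 5), ScoreCategory.MEDIUM),
            (0, (4, 5), ScoreCategory.LOW),
            (5, (4, 5), ScoreCategory.HIGH),
        ],
    )
    def test_examples(self, score, cutpoints, expected):
        assert categorize(score, cutpoints) == expected

    def test_partition(self):
        for s in range(50):
            assert categorize(s, (8, 12)) in list(ScoreCategory)

    def test_bad_cutpoints(self):
        with pytest.raises(ValueError):
            categorize(3, (5, 5))


class TestTreatmentRule:
    def test_validation(self):
        with pytest.raises(ValueError):
            TreatmentRule(())
        with pytest.raises(ValueError):
            TreatmentRule(((0, 8),))
        with pytest.raises(ValueError):
            TreatmentRule(((2, 0),))

    def test_two_consecutive_eight(self):
        rule = TreatmentRule(((2, 8), (1, 12)))
        assert first_treatment_day([(1, 7), (1, 8), (2, 8)], rule) == 2

    def test_single_twelve(self):
        rule = TreatmentRule(((2, 8), (1, 12)))
        assert first_treatment_day([(1, 12)], rule) == 1

    def test_alternating_never_triggers(self):
        rule = TreatmentRule(((3, 8), (2, 12)))
        scores = [(1, 8), (1, 7), (2, 8), (2, 7), (3, 8)]
        assert first_treatment_day(scores, rule) is None

    def test_run_crosses_day_boundary(self):
        rule = TreatmentRule(((3, 8),))
        scores = [(1, 8), (2, 9), (2, 10)]
        assert first_treatment_day(scores, rule) == 2

    def test_empty_sequence(self):
        assert first_treatment_day([], TreatmentRule(((1, 8),))) is None


class TestExtractAnalysisRow:
    RULE = TreatmentRule(((2, 8), (1, 12)))

    @staticmethod
    def _assessment(day, idx, score_items):
        return record(score_items, day_of_life=day, assessment_index=idx)

    def test_highest_score_on_treatment_day(self):
        # day-2 scores 9, 11, 10 after triggering; the 11 is chosen
        grades_9 = {"tremors_undisturbed": "moderate_severe", "generalized_convulsions": "present"}
        grades_11 = {"generalized_convulsions": "present", "tremors_undisturbed": "moderate_severe", "increased_muscle_tone": "present"}
        grades_10 = {"generalized_convulsions": "present", "tremors_undisturbed": "mild", "increased_muscle_tone": "present"}
        hist = [
            self._assessment(1, 1, {"generalized_convulsions": "present", "vomiting": "projectile"}),  # 8
            self._assessment(2, 1, grades_9),
            self._assessment(2, 2, grades_11),
            self._assessment(2, 3, grades_10),
        ]
        row = extract_analysis_row("n", "c", hist, self.RULE)
        assert row.treated and row.analysis_day == 2
        assert row.original_score == 11
        assert row.flags["increased_muscle_tone"]

    def test_untreated_uses_day_three(self):
        hist = [
            self._assessment(1, 1, {}),
            self._assessment(3, 1, {"increased_muscle_tone": "present", "stools": "watery"}),
        ]
        row = extract_analysis_row("n", "c", hist, self.RULE)
        assert not row.treated
        assert row.analysis_day == 3
        assert row.original_score == 5

    def test_tie_prefers_earlier_assessment(self):
        hist = [
            self._assessment(3, 1, {"excoriation": "present"}),
            self._assessment(3, 2, {"sweating": "present"}),
        ]
        row = extract_analysis_row("n", "c", hist, self.RULE)
        assert row.flags["excoriation"] and not row.flags["sweating"]

    def test_missing_analysis_day_raises(self):
        hist = [self._assessment(1, 1, {})]
        with pytest.raises(MissingAnalysisDayError):
            extract_analysis_row("n", "c", hist, self.RULE)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            record({}, day_of_life=0)
        with pytest.raises(ValueError):
            record({}, assessment_index=0)
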