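"""Data model and scoring operations for the 21-item neonatal abstinence
scoring tool, its binary (present/absent) simplification, and the 8-item
simplified scale.

The original instrument scores 21 graded signs of neonatal withdrawal, each
level carrying an integer weight from 1 to 5; the total is the severity
score. Dichotomizing each item ("coded as having the sign if any level was
recorded") yields 21 binary signs, two of which (the tremor items) merge
into a single "any tremors" indicator on the 8-item simplified scale. The
simplified score is the unweighted count of 8 binary signs, range 0-8.

This module also implements the site treatment-initiation rules (k
consecutive scores at or above a threshold) and extraction of the single
analysis point per neonate: the highest-scoring assessment on the first
treatment day, or on day 3 of life for neonates never treated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GradeLevel",
    "ItemDefinition",
    "AssessmentRecord",
    "BinaryAssessment",
    "AnalysisRow",
    "TreatmentRule",
    "ScoreCategory",
    "SchemaError",
    "MissingAnalysisDayError",
    "ITEM_DEFINITIONS",
    "BINARY_ITEMS",
    "SIMPLIFIED_ITEMS",
    "ANY_TREMORS",
    "TREMOR_ITEMS",
    "ORIGINAL_CUTPOINTS",
    "load_item_definitions",
    "score_original",
    "binarize",
    "score_simplified",
    "simplified_score_from_flags",
    "categorize",
    "first_treatment_day",
    "extract_analysis_row",
]


class SchemaError(ValueError):
    """An assessment references an unknown item or grade label."""


class MissingAnalysisDayError(ValueError):
    """A neonate has no assessment on its analysis day."""


@dataclass(frozen=True)
class GradeLevel:
    label: str
    weight: int


@dataclass(frozen=True)
class ItemDefinition:
    """One graded item: ordered severity levels with integer weights and the
    binary sign the item collapses to under dichotomization."""

    item_id: str
    label: str
    levels: tuple[GradeLevel, ...]
    binary_group: str

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"{self.item_id}: no levels")
        weights = [lv.weight for lv in self.levels]
        if any(w <= 0 or w != int(w) for w in weights):
            raise ValueError(f"{self.item_id}: weights must be positive integers")
        if any(b <= a for a, b in zip(weights, weights[1:])):
            raise ValueError(f"{self.item_id}: weights must increase with severity")

    def weight_of(self, grade_label: str) -> int:
        for lv in self.levels:
            if lv.label == grade_label:
                return lv.weight
        raise SchemaError(f"unknown grade {grade_label!r} for item {self.item_id!r}")

    @property
    def max_weight(self) -> int:
        return self.levels[-1].weight


def load_item_definitions() -> dict[str, ItemDefinition]:
    """Load the versioned 21-item definition resource."""
    raw = json.loads(
        resources.files("fnast8.data").joinpath("item_definitions.json").read_text()
    )
    defs: dict[str, ItemDefinition] = {}
    for entry in raw["items"]:
        defs[entry["item_id"]] = ItemDefinition(
            item_id=entry["item_id"],
            label=entry["label"],
            levels=tuple(GradeLevel(lbl, int(w)) for lbl, w in entry["levels"]),
            binary_group=entry["binary_group"],
        )
    return defs


ITEM_DEFINITIONS: dict[str, ItemDefinition] = load_item_definitions()

#: Binary sign identifiers, in instrument order. One per graded item.
BINARY_ITEMS: tuple[str, ...] = tuple(
    d.binary_group for d in ITEM_DEFINITIONS.values()
)

TREMOR_ITEMS: tuple[str, str] = ("tremors_disturbed", "tremors_undisturbed")
ANY_TREMORS = "any_tremors"

#: The 8 items of the simplified scale, each scored 0/1. "any_tremors" is
#: present when either tremor sign is.
SIMPLIFIED_ITEMS: tuple[str, ...] = (
    "sleeps_lt_3h",
    ANY_TREMORS,
    "increased_muscle_tone",
    "temp_ge_37_2",
    "resp_gt_60",
    "excessive_sucking",
    "poor_feeding",
    "regurgitation",
)

#: Predetermined category cutpoints on the original scale.
ORIGINAL_CUTPOINTS: tuple[int, int] = (8, 12)


@dataclass(frozen=True)
class AssessmentRecord:
    """One scoring event: per-item grades for a neonate at a point in time.

    ``grades`` maps item_id -> grade label; absent items contribute nothing.
    Day of birth is day 1.
    """

    neonate_id: str
    cohort_id: str
    day_of_life: int
    assessment_index: int
    grades: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day_of_life < 1:
            raise ValueError("day_of_life must be >= 1 (day of birth = 1)")
        if self.assessment_index < 1:
            raise ValueError("assessment_index must be >= 1")


@dataclass(frozen=True)
class BinaryAssessment:
    """Dichotomized view of one assessment: present/absent flag per binary
    sign, plus the original weighted score of the source record."""

    flags: Mapping[str, bool]
    original_score: int


@dataclass(frozen=True)
class AnalysisRow:
    """One neonate's single analysis point: binary flags, original score,
    cohort, and treatment status."""

    neonate_id: str
    cohort_id: str
    flags: Mapping[str, bool]
    original_score: int
    treated: bool
    analysis_day: int

    @property
    def simplified_score(self) -> int:
        return simplified_score_from_flags(self.flags)


@dataclass(frozen=True)
class TreatmentRule:
    """Treatment triggers when any clause (k, threshold) is satisfied by k
    consecutive assessments all scoring >= threshold."""

    clauses: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("rule needs at least one clause")
        for k, threshold in self.clauses:
            if k < 1:
                raise ValueError("consecutive count k must be >= 1")
            if threshold <= 0:
                raise ValueError("threshold must be positive")


class ScoreCategory(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


def _check_grades(grades: Mapping[str, str],
                  defs: Mapping[str, ItemDefinition]) -> None:
    for item_id, grade in grades.items():
        if item_id not in defs:
            raise SchemaError(f"unknown item {item_id!r}")
        defs[item_id].weight_of(grade)  # raises on unknown grade


def score_original(a: AssessmentRecord,
                   defs: Optional[Mapping[str, ItemDefinition]] = None) -> int:
    """Weighted total: sum of the recorded grade's weight over all items
    (absent items contribute 0)."""
    defs = ITEM_DEFINITIONS if defs is None else defs
    _check_grades(a.grades, defs)
    return sum(defs[item].weight_of(grade) for item, grade in a.grades.items())


def binarize(a: AssessmentRecord,
             defs: Optional[Mapping[str, ItemDefinition]] = None) -> BinaryAssessment:
    """Dichotomize: each binary sign is present iff any constituent grade of
    its graded item is recorded."""
    defs = ITEM_DEFINITIONS if defs is None else defs
    _check_grades(a.grades, defs)
    flags = {b: False for b in BINARY_ITEMS}
    for item_id in a.grades:
        flags[defs[item_id].binary_group] = True
    return BinaryAssessment(flags=flags, original_score=score_original(a, defs))


def simplified_score_from_flags(flags: Mapping[str, bool]) -> int:
    """Simplified 0-8 score from binary sign flags. Accepts either separate
    tremor flags or a precomputed ``any_tremors`` flag."""
    total = 0
    for item in SIMPLIFIED_ITEMS:
        if item == ANY_TREMORS:
            present = bool(flags.get(ANY_TREMORS, False)) or any(
                flags.get(t, False) for t in TREMOR_ITEMS
            )
        else:
            present = bool(flags.get(item, False))
        total += int(present)
    return total


def score_simplified(b: BinaryAssessment) -> int:
    return simplified_score_from_flags(b.flags)


def categorize(score: int, cutpoints: tuple[int, int] = ORIGINAL_CUTPOINTS) -> ScoreCategory:
    """Partition a score into low [0, c1), medium [c1, c2), high [c2, inf)."""
    c1, c2 = cutpoints
    if not c1 < c2:
        raise ValueError(f"cutpoints must satisfy c1 < c2, got {cutpoints}")
    if score < c1:
        return ScoreCategory.LOW
    if score < c2:
        return ScoreCategory.MEDIUM
    return ScoreCategory.HIGH


def first_treatment_day(scores: Sequence[tuple[int, int]],
                        rule: TreatmentRule) -> Optional[int]:
    """Day on which a treatment rule first triggers.

    ``scores`` is the chronologically ordered sequence of (day, score).
    Returns the day of the final assessment of the earliest run of k
    consecutive scores all >= threshold for any clause; ``None`` if the rule
    never triggers. Runs may cross day boundaries.
    """
    run_lengths = [0] * len(rule.clauses)
    for day, score in scores:
        for i, (k, threshold) in enumerate(rule.clauses):
            run_lengths[i] = run_lengths[i] + 1 if score >= threshold else 0
            if run_lengths[i] >= k:
                return day
    return None


def extract_analysis_row(neonate_id: str,
                         cohort_id: str,
                         assessments: Iterable[AssessmentRecord],
                         rule: TreatmentRule,
                         defs: Optional[Mapping[str, ItemDefinition]] = None,
                         untreated_day: int = 3) -> AnalysisRow:
    """Extract a neonate's single analysis point.

    Treated neonates (the rule triggers on their score sequence) contribute
    the highest-scoring assessment on the first treatment day; untreated
    neonates the highest-scoring assessment on ``untreated_day``. Ties go to
    the earlier assessment.
    """
    defs = ITEM_DEFINITIONS if defs is None else defs
    ordered = sorted(assessments, key=lambda a: (a.day_of_life, a.assessment_index))
    if not ordered:
        raise MissingAnalysisDayError(f"{neonate_id}: no assessments")
    scores = [(a.day_of_life, score_original(a, defs)) for a in ordered]
    treatment_day = first_treatment_day(scores, rule)
    treated = treatment_day is not None
    analysis_day = treatment_day if treated else untreated_day
    day_scores = [
        (s, a) for (d, s), a in zip(scores, ordered) if d == analysis_day
    ]
    if not day_scores:
        raise MissingAnalysisDayError(
            f"{neonate_id}: no assessment on analysis day {analysis_day}"
        )
    best_score = max(s for s, _ in day_scores)
    chosen = next(a for s, a in day_scores if s == best_score)
    return AnalysisRow(
        neonate_id=neonate_id,
        cohort_id=cohort_id,
        flags=binarize(chosen, defs).flags,
        original_score=best_score,
        treated=treated,
        analysis_day=analysis_day,
    )
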