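"""Strict CSV / JSON input and output for assessment tables, analysis-row
tables, and stage reports. Parsing never coerces silently; malformed input
raises with the offending line or value named."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BINARY_ITEMS,
    ITEM_DEFINITIONS,
    AnalysisRow,
    AssessmentRecord,
    SchemaError,
)

__all__ = [
    "ASSESSMENT_COLUMNS",
    "read_assessments",
    "write_assessments",
    "records_to_frame",
    "frame_to_records",
    "analysis_rows_to_frame",
    "frame_to_analysis_rows",
    "read_analysis_rows",
    "write_analysis_rows",
    "add_any_tremors",
    "simplified_scores",
    "write_truth_log",
]

ASSESSMENT_COLUMNS = [
    "neonate_id",
    "cohort_id",
    "day_of_life",
    "assessment_index",
    "item_id",
    "grade_label",
]

_ANALYSIS_META = ["neonate_id", "cohort_id", "treated", "analysis_day", "original_score"]


def records_to_frame(records: Iterable[AssessmentRecord]) -> pd.DataFrame:
    """Long-form table: one row per (assessment, recorded item). An
    assessment with no recorded items emits one row with empty item_id."""
    rows = []
    for rec in records:
        base = dict(
            neonate_id=rec.neonate_id,
            cohort_id=rec.cohort_id,
            day_of_life=rec.day_of_life,
            assessment_index=rec.assessment_index,
        )
        if rec.grades:
            for item, grade in rec.grades.items():
                rows.append({**base, "item_id": item, "grade_label": grade})
        else:
            rows.append({**base, "item_id": "", "grade_label": ""})
    return pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[AssessmentRecord]:
    records = []
    keys = ["neonate_id", "cohort_id", "day_of_life", "assessment_index"]
    for (nid, cid, day, idx), grp in frame.groupby(keys, sort=True):
        grades = {}
        for _, row in grp.iterrows():
            item = row["item_id"]
            if item == "":
                continue
            if item in grades:
                raise SchemaError(
                    f"duplicate grade for item {item!r} at assessment "
                    f"({nid}, day {day}, index {idx})"
                )
            grades[item] = row["grade_label"]
        records.append(
            AssessmentRecord(
                neonate_id=str(nid),
                cohort_id=str(cid),
                day_of_life=int(day),
                assessment_index=int(idx),
                grades=grades,
            )
        )
    return records


def read_assessments(path: "str | Path") -> list[AssessmentRecord]:
    """Read the long-form assessment CSV, validating schema, item ids, and
    grade labels; errors name the offending line (1-based, counting the
    header)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ASSESSMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("day_of_life", "assessment_index"):
        bad = ~frame[col].str.fullmatch(r"\d+")
        if bad.any():
            line = int(frame.index[bad][0]) + 2
            raise SchemaError(f"{path}:{line}: non-integer {col} {frame.loc[bad, col].iloc[0]!r}")
        frame[col] = frame[col].astype(int)
    for pos, row in frame.iterrows():
        item = row["item_id"]
        if item == "":
            continue
        if item not in ITEM_DEFINITIONS:
            raise SchemaError(f"{path}:{int(pos) + 2}: unknown item_id {item!r}")
        try:
            ITEM_DEFINITIONS[item].weight_of(row["grade_label"])
        except SchemaError as exc:
            raise SchemaError(f"{path}:{int(pos) + 2}: {exc}") from None
    dup_keys = ["neonate_id", "day_of_life", "assessment_index", "item_id"]
    nonempty = frame[frame["item_id"] != ""]
    dups = nonempty.duplicated(dup_keys, keep=False)
    if dups.any():
        first = nonempty[dups].iloc[0]
        raise SchemaError(
            f"{path}: duplicated (neonate, day, index, item): "
            f"({first['neonate_id']}, {first['day_of_life']}, "
            f"{first['assessment_index']}, {first['item_id']})"
        )
    return frame_to_records(frame)


def write_assessments(records: Iterable[AssessmentRecord], path: "str | Path") -> None:
    records_to_frame(records).to_csv(path, index=False)


def analysis_rows_to_frame(rows: Iterable[AnalysisRow]) -> pd.DataFrame:
    data = []
    for r in rows:
        entry = dict(
            neonate_id=r.neonate_id,
            cohort_id=r.cohort_id,
            treated=bool(r.treated),
            analysis_day=int(r.analysis_day),
            original_score=int(r.original_score),
        )
        for item in BINARY_ITEMS:
            entry[item] = int(bool(r.flags.get(item, False)))
        data.append(entry)
    return pd.DataFrame(data, columns=_ANALYSIS_META + list(BINARY_ITEMS))


def frame_to_analysis_rows(frame: pd.DataFrame) -> list[AnalysisRow]:
    out = []
    for _, row in frame.iterrows():
        out.append(
            AnalysisRow(
                neonate_id=str(row["neonate_id"]),
                cohort_id=str(row["cohort_id"]),
                flags={item: bool(row[item]) for item in BINARY_ITEMS},
                original_score=int(row["original_score"]),
                treated=bool(row["treated"]),
                analysis_day=int(row["analysis_day"]),
            )
        )
    return out


def write_analysis_rows(frame: pd.DataFrame, path: "str | Path") -> None:
    frame.to_csv(path, index=False)


def read_analysis_rows(path: "str | Path") -> pd.DataFrame:
    """Read the wide analysis-row CSV; validates columns and 0/1 flags."""
    frame = pd.read_csv(path)
    missing = [c for c in _ANALYSIS_META + list(BINARY_ITEMS) if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if frame["neonate_id"].duplicated().any():
        dup = frame.loc[frame["neonate_id"].duplicated(), "neonate_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate neonate_id {dup!r}")
    for item in BINARY_ITEMS:
        vals = frame[item]
        if not vals.isin([0, 1]).all():
            bad = vals[~vals.isin([0, 1])].iloc[0]
            raise SchemaError(f"{path}: non-binary value {bad!r} in column {item!r}")
    frame["treated"] = frame["treated"].astype(bool)
    return frame


def add_any_tremors(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the combined 'any_tremors' indicator column."""
    out = frame.copy()
    out["any_tremors"] = (
        (frame["tremors_disturbed"].astype(int) | frame["tremors_undisturbed"].astype(int))
    ).astype(np.int64)
    return out


def simplified_scores(frame: pd.DataFrame) -> np.ndarray:
    """Simplified 0-8 score per analysis row."""
    from .core import ANY_TREMORS, SIMPLIFIED_ITEMS, TREMOR_ITEMS

    total = np.zeros(len(frame), dtype=np.int64)
    for item in SIMPLIFIED_ITEMS:
        if item == ANY_TREMORS:
            total += (
                frame[TREMOR_ITEMS[0]].astype(int) | frame[TREMOR_ITEMS[1]].astype(int)
            ).to_numpy()
        else:
            total += frame[item].astype(int).to_numpy()
    return total


def write_truth_log(truth: pd.DataFrame, path: "str | Path") -> None:
    """Truth log as JSON-lines, one object per neonate."""
    with open(path, "w") as fh:
        for _, row in truth.iterrows():
            fh.write(json.dumps(row.to_dict()) + "\n")
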