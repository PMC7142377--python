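"""Packaged published summary tables used as fixtures and defaults:
per-cohort endorsement counts of the binary signs and the 3x3 severity
category crosstab of the original versus the simplified scale."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "endorsement_counts",
    "cohort_sizes",
    "derivation_cohorts",
    "validation_cohort",
    "endorsement_rates",
    "category_crosstab",
    "TREATED_TOTAL",
]


@lru_cache(maxsize=None)
def _endorsement_resource() -> dict:
    return json.loads(
        resources.files("fnast8.data").joinpath("endorsement_counts.json").read_text()
    )


@lru_cache(maxsize=None)
def _crosstab_resource() -> dict:
    return json.loads(
        resources.files("fnast8.data").joinpath("category_crosstab.json").read_text()
    )


def cohort_sizes() -> dict[str, int]:
    return dict(_endorsement_resource()["cohort_sizes"])


def derivation_cohorts() -> list[str]:
    return list(_endorsement_resource()["derivation_cohorts"])


def validation_cohort() -> str:
    return _endorsement_resource()["validation_cohort"]


def endorsement_counts(cohorts: list[str] | None = None) -> dict[str, dict[str, tuple[int, int]]]:
    """item_id -> cohort -> (endorsed, total). Defaults to the three
    derivation cohorts; pass an explicit list to include the validation
    cohort."""
    res = _endorsement_resource()
    cohorts = derivation_cohorts() if cohorts is None else cohorts
    sizes = res["cohort_sizes"]
    return {
        item: {c: (counts[c], sizes[c]) for c in cohorts}
        for item, counts in res["counts"].items()
    }


def endorsement_rates(cohorts: list[str] | None = None) -> dict[str, dict[str, float]]:
    """item_id -> cohort -> endorsement rate, computed from counts."""
    return {
        item: {c: e / t for c, (e, t) in per.items()}
        for item, per in endorsement_counts(cohorts).items()
    }


def category_crosstab() -> np.ndarray:
    """The published 3x3 category agreement table (rows: original low,
    medium, high; columns: simplified low, medium, high)."""
    return np.asarray(_crosstab_resource()["counts"], dtype=float)


TREATED_TOTAL: int = 238
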