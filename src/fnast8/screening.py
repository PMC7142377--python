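"""Cross-cohort item screening: chi-square homogeneity tests, maximum
pairwise endorsement-rate differences, endorsement concordance (AUC), and
the exclusion filter (never-observed items and items differing by more than
50 percentage points among cohorts)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BINARY_ITEMS

__all__ = [
    "ItemScreenResult",
    "chi2_homogeneity",
    "max_pp_difference",
    "endorsement_auc",
    "screen_items",
    "screen_counts",
    "format_p",
    "HETEROGENEITY_PP_THRESHOLD",
]

#: Items whose cohort endorsement rates differ by more than this many
#: percentage points are excluded from model building.
HETEROGENEITY_PP_THRESHOLD = 50.0


@dataclass
class ItemScreenResult:
    item_id: str
    counts: dict[str, tuple[int, int]]  # cohort -> (endorsed, total)
    rates: dict[str, float]
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    max_pp_difference: float
    auc: Optional[float]
    auc_ci: Optional[tuple[float, float]]
    excluded: bool
    exclusion_reason: Optional[str]  # "never_observed" | "heterogeneity"
    zero_variance: bool = False  # endorsed by every neonate overall


def chi2_homogeneity(counts: Sequence[tuple[int, int]]) -> tuple[float, int, float]:
    """Pearson chi-square test of equal endorsement proportions across
    cohorts on the 2 x k endorsed/not-endorsed table, no continuity
    correction; df = k - 1.

    An item endorsed by everyone or no one overall carries no information:
    statistic 0, p = 1.
    """
    counts = list(counts)
    if len(counts) < 2:
        raise ValueError("need at least 2 cohorts")
    if any(t <= 0 for _, t in counts):
        raise ValueError("cohort totals must be positive")
    endorsed = sum(e for e, _ in counts)
    total = sum(t for _, t in counts)
    k = len(counts)
    if endorsed == 0 or endorsed == total:
        return 0.0, k - 1, 1.0
    table = np.array([[e for e, _ in counts], [t - e for e, t in counts]])
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def max_pp_difference(rates: Sequence[float]) -> float:
    """Largest pairwise difference of cohort endorsement rates, in
    percentage points."""
    rates = list(rates)
    if len(rates) < 2:
        raise ValueError("need at least 2 cohorts")
    return 100.0 * (max(rates) - min(rates))


def endorsement_auc(
    counts: Sequence[tuple[int, int]],
) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    """Concordance between endorsed and non-endorsed neonates when every
    neonate is scored by its cohort's endorsement rate.

    AUC = [#(endorsed, non-endorsed) pairs with rate_endorsed > rate_non +
    half the tied pairs] / (n_endorsed * n_non). Degenerate when there are
    no endorsed or no non-endorsed neonates: returns (None, None).

    The confidence interval uses the Hanley-McNeil variance.
    """
    counts = list(counts)
    rates = [e / t for e, t in counts]
    pos = [(r, e) for (e, _), r in zip(counts, rates)]
    neg = [(r, t - e) for (e, t), r in zip(counts, rates)]
    n_pos = sum(n for _, n in pos)
    n_neg = sum(n for _, n in neg)
    if n_pos == 0 or n_neg == 0:
        return None, None
    num = 0.0
    for rp, cp in pos:
        for rn, cn in neg:
            if rp > rn:
                num += cp * cn
            elif rp == rn:
                num += 0.5 * cp * cn
    auc = num / (n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), ci


def screen_counts(
    counts_by_item: dict[str, dict[str, tuple[int, int]]],
    pp_threshold: float = HETEROGENEITY_PP_THRESHOLD,
) -> list[ItemScreenResult]:
    """Screen items given per-cohort (endorsed, total) counts.

    Exclusions: overall count zero ("never_observed") or maximum pairwise
    rate difference strictly above ``pp_threshold`` percentage points
    ("heterogeneity"). Rates are computed from counts, not from rounded
    percentages. Items endorsed by every neonate are retained but flagged
    zero-variance for the regression stage.
    """
    results = []
    for item_id, per_cohort in counts_by_item.items():
        pairs = list(per_cohort.values())
        rates = {c: e / t for c, (e, t) in per_cohort.items()}
        stat, df, p = chi2_homogeneity(pairs)
        pp = max_pp_difference(list(rates.values()))
        auc, ci = endorsement_auc(pairs)
        endorsed = sum(e for e, _ in pairs)
        total = sum(t for _, t in pairs)
        if endorsed == 0:
            excluded, reason = True, "never_observed"
        elif pp > pp_threshold:
            excluded, reason = True, "heterogeneity"
        else:
            excluded, reason = False, None
        results.append(
            ItemScreenResult(
                item_id=item_id,
                counts=dict(per_cohort),
                rates=rates,
                chi2_stat=stat,
                chi2_df=df,
                chi2_p=p,
                max_pp_difference=pp,
                auc=auc,
                auc_ci=ci,
                excluded=excluded,
                exclusion_reason=reason,
                zero_variance=(endorsed == total),
            )
        )
    return results


def screen_items(
    rows: pd.DataFrame,
    items: Sequence[str] = BINARY_ITEMS,
    cohort_col: str = "cohort_id",
    pp_threshold: float = HETEROGENEITY_PP_THRESHOLD,
) -> tuple[list[ItemScreenResult], list[str]]:
    """Screen binary items on an analysis-row table (one row per neonate,
    0/1 column per item). Returns per-item results and the surviving item
    list, in input order."""
    if rows[cohort_col].nunique() < 2:
        raise ValueError("screening requires at least 2 cohorts")
    sizes = rows.groupby(cohort_col, sort=False).size()
    counts_by_item = {}
    for item in items:
        endorsed = rows.groupby(cohort_col, sort=False)[item].sum()
        counts_by_item[item] = {
            c: (int(endorsed[c]), int(sizes[c])) for c in sizes.index
        }
    results = screen_counts(counts_by_item, pp_threshold=pp_threshold)
    survivors = [r.item_id for r in results if not r.excluded]
    return results, survivors


def format_p(p: float) -> str:
    """P-value display convention of the source tables: '<.001' below
    0.001, 3 decimals below 0.01, otherwise 2 decimals, no leading zero."""
    if p < 0.001:
        return "<.001"
    if p < 0.0095:  # rounds to 3 decimals below .01
        return f"{p:.3f}".lstrip("0")
    return f"{p:.2f}".lstrip("0")
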