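"""Threshold calibration of the simplified scale against the original
scale's predetermined severity categories, via linear-weighted kappa over an
exhaustive cutpoint grid, plus external-cohort validation of the selected
items."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ORIGINAL_CUTPOINTS
from .logistic import FitResult, build_design, fit_logistic, model_auc

__all__ = [
    "CalibrationResult",
    "DegenerateTableError",
    "weighted_kappa",
    "linear_weights",
    "quadratic_weights",
    "crosstab_categories",
    "select_thresholds",
    "validate_external",
    "SIMPLIFIED_SCORE_MAX",
]

SIMPLIFIED_SCORE_MAX = 8
_Z975 = 1.959963984540054


class DegenerateTableError(ValueError):
    """Agreement is undefined: chance agreement equals 1."""


def linear_weights(r: int) -> np.ndarray:
    """Cicchetti-Allison agreement weights w_ij = 1 - |i-j|/(r-1)."""
    idx = np.arange(r)
    return 1.0 - np.abs(np.subtract.outer(idx, idx)) / (r - 1)


def quadratic_weights(r: int) -> np.ndarray:
    idx = np.arange(r)
    return 1.0 - (np.subtract.outer(idx, idx) / (r - 1)) ** 2


def weighted_kappa(
    table: np.ndarray,
    weights: "str | np.ndarray" = "linear",
) -> tuple[float, tuple[float, float], float]:
    """Weighted Cohen's kappa on a square contingency table of counts.

    kappa_w = (P_o - P_e) / (1 - P_e) with P_o = sum w_ij p_ij and
    P_e = sum w_ij row_i col_j / n^2. ``weights`` may be "linear",
    "quadratic", "unweighted" (identity), or an explicit matrix. The
    standard error is the Fleiss-Cohen-Everitt large-sample formula; the CI
    is kappa +/- 1.96 se, clipped to [-1, 1].
    """
    table = np.asarray(table, dtype=float)
    r, c = table.shape
    if r != c:
        raise ValueError("table must be square")
    n = table.sum()
    if n <= 0:
        raise ValueError("empty table")
    if isinstance(weights, str):
        w = {
            "linear": linear_weights,
            "quadratic": quadratic_weights,
            "unweighted": np.eye,
        }[weights](r)
    else:
        w = np.asarray(weights, dtype=float)
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if pe >= 1.0 - 1e-12:
        raise DegenerateTableError("chance agreement P_e = 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt large-sample variance
    wbar_row = w @ col  # wbar_i. = sum_j col_j w_ij
    wbar_col = row @ w  # wbar_.j = sum_i row_i w_ij
    inner = (
        p * (w * (1.0 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - po)) ** 2
    ).sum()
    var = (inner - (po * pe - 2.0 * pe + po) ** 2) / (n * (1.0 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(-1.0, kappa - _Z975 * se), min(1.0, kappa + _Z975 * se))
    return float(kappa), ci, se


def crosstab_categories(
    original_scores: Sequence[int],
    simplified_scores: Sequence[int],
    cutpoints: tuple[int, int],
    original_cutpoints: tuple[int, int] = ORIGINAL_CUTPOINTS,
) -> np.ndarray:
    """3x3 counts of (original category, simplified category); rows are
    original low/medium/high, columns simplified low/medium/high."""
    orig = np.asarray(original_scores)
    simp = np.asarray(simplified_scores)
    if orig.shape != simp.shape:
        raise ValueError("score vectors must align")
    o_cat = np.digitize(orig, original_cutpoints)
    s_cat = np.digitize(simp, cutpoints)
    table = np.zeros((3, 3))
    np.add.at(table, (o_cat, s_cat), 1)
    return table


@dataclass
class CalibrationResult:
    crosstab: np.ndarray
    kappa: float
    kappa_ci: tuple[float, float]
    thresholds: tuple[int, int]
    grid: pd.DataFrame  # columns t1, t2, kappa (NaN where degenerate)


def select_thresholds(
    original_scores: Sequence[int],
    simplified_scores: Sequence[int],
    original_cutpoints: tuple[int, int] = ORIGINAL_CUTPOINTS,
    score_max: int = SIMPLIFIED_SCORE_MAX,
    weights: str = "linear",
) -> CalibrationResult:
    """Exhaustive grid search for simplified-scale cutpoints maximizing
    weighted kappa with the original-scale categories.

    The grid is all integer pairs 1 <= t1 < t2 <= score_max (28 pairs for a
    0-8 scale); ties prefer the smallest t1, then the smallest t2. The full
    grid is retained for reporting.
    """
    simp = np.asarray(simplified_scores)
    if len(np.unique(simp)) < 2:
        raise DegenerateTableError("simplified scores are constant")
    rows = []
    best = None
    for t1 in range(1, score_max):
        for t2 in range(t1 + 1, score_max + 1):
            table = crosstab_categories(
                original_scores, simp, (t1, t2), original_cutpoints
            )
            try:
                kappa, ci, _ = weighted_kappa(table, weights)
            except DegenerateTableError:
                rows.append(dict(t1=t1, t2=t2, kappa=np.nan))
                continue
            rows.append(dict(t1=t1, t2=t2, kappa=kappa))
            if best is None or kappa > best[0] + 1e-15:
                best = (kappa, ci, (t1, t2), table)
    if best is None:
        raise DegenerateTableError("kappa undefined for every cutpoint pair")
    kappa, ci, thresholds, table = best
    return CalibrationResult(
        crosstab=table,
        kappa=kappa,
        kappa_ci=ci,
        thresholds=thresholds,
        grid=pd.DataFrame(rows),
    )


def validate_external(
    items: Sequence[str],
    rows: pd.DataFrame,
    outcome_col: str = "treated",
) -> tuple[Optional[float], Optional[tuple[float, float]], FitResult]:
    """Refit a logistic model of the outcome on the selected items in an
    independent single-cohort table and report its concordance with a
    Hanley-McNeil interval."""
    missing = [c for c in items if c not in rows.columns]
    if missing:
        raise KeyError(f"validation table lacks item columns: {missing}")
    usable = []
    for item in items:
        vals = rows[item].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            warnings.warn(f"validation: dropping constant item column {item!r}")
        else:
            usable.append(item)
    y, X, names = build_design(rows, usable, cohort_col=None,
                               outcome_col=outcome_col)
    fit = fit_logistic(y, X, names)
    auc = model_auc(fit.fitted, y)
    if auc is None:
        return None, None, fit
    n1 = int(y.sum())
    n0 = len(y) - n1
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    half = _Z975 * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half)), fit
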