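"""Binary logistic regression by iteratively reweighted least squares and
forward stepwise item selection with forced cohort adjustment.

Implemented from first principles (rather than delegating to a statistics
library) because the selection procedure needs tight control over the fit
internals: likelihood-ratio and score entry tests against the current
model, Wald removal tests, step-halving with a monotone log-likelihood
guarantee, a separation guard, and optional Firth penalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

__all__ = [
    "FitResult",
    "StepwiseTrace",
    "StepwiseStep",
    "SingularDesignError",
    "NonConvergenceError",
    "fit_logistic",
    "lr_test",
    "score_test",
    "wald_tests",
    "model_auc",
    "build_design",
    "cohort_dummies",
    "univariate_item_models",
    "forward_stepwise",
    "SEPARATION_BETA_BOUND",
]

SEPARATION_BETA_BOUND = 15.0
_Z975 = 1.959963984540054


class SingularDesignError(np.linalg.LinAlgError):
    """The information matrix is singular; names the offending columns."""


class NonConvergenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    params: np.ndarray
    names: list[str]
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    separation: bool
    fitted: np.ndarray
    n_obs: int
    auc: Optional[float] = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def wald_p(self) -> np.ndarray:
        """Two-sided Wald p-values per coefficient. Suppressed (NaN) for
        non-converged fits."""
        if not self.converged:
            return np.full(len(self.params), np.nan)
        z = self.params / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def odds_ratios(self) -> pd.DataFrame:
        """exp(beta) with 95% Wald intervals, one row per coefficient."""
        se = self.se
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.params,
                "se": se,
                "or": np.exp(self.params),
                "or_ci_low": np.exp(self.params - _Z975 * se),
                "or_ci_high": np.exp(self.params + _Z975 * se),
                "p": self.wald_p(),
            }
        )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), stable via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _name_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X)
    return [names[j] for j in sorted(piv[rank:])]


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    names: Optional[Sequence[str]] = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_rel_tol: float = 1e-10,
    firth: bool = False,
) -> FitResult:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Convergence when the maximum absolute score component drops below
    ``score_tol`` or the relative log-likelihood change below
    ``ll_rel_tol``. Any |beta| exceeding 15 flags probable separation.
    With ``firth=True`` the Firth bias-reduction penalty is applied, which
    yields finite estimates under separation.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if n <= p:
        raise ValueError(f"n={n} must exceed number of parameters p={p}")

    beta = np.zeros(p)
    eta = X @ beta
    ll = _penalized_ll(y, eta, X, firth)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        prob = expit(eta)
        w = np.clip(prob * (1.0 - prob), 1e-10, None)
        info = X.T @ (X * w[:, None])
        if firth:
            h = _hat_diag(X, w, info, names)
            g = X.T @ (y - prob + h * (0.5 - prob))
        else:
            g = X.T @ (y - prob)
        if np.max(np.abs(g)) < score_tol:
            converged = True
            break
        try:
            delta = linalg.solve(info, g, assume_a="pos")
        except linalg.LinAlgError:
            raise SingularDesignError(
                f"singular information matrix; collinear columns: "
                f"{_name_collinear(X, names)}"
            )
        if not np.all(np.isfinite(delta)):
            raise SingularDesignError(
                f"non-finite update; collinear columns: {_name_collinear(X, names)}"
            )
        # step-halve until the (penalized) log-likelihood does not decrease
        step = 1.0
        for _ in range(30):
            beta_new = beta + step * delta
            ll_new = _penalized_ll(y, X @ beta_new, X, firth)
            if ll_new >= ll:
                break
            step *= 0.5
        else:
            converged = True  # no uphill step left: at a maximum
            break
        beta, eta = beta_new, X @ beta_new
        if np.max(np.abs(beta)) > SEPARATION_BETA_BOUND:
            separation = True
        if abs(ll_new - ll) < ll_rel_tol * (abs(ll) + 1e-300):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    prob = expit(eta)
    w = np.clip(prob * (1.0 - prob), 1e-10, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if separation:
        converged = False if not firth else converged
    return FitResult(
        params=beta,
        names=names,
        cov=cov,
        loglik=_loglik(y, eta),
        converged=converged,
        n_iter=it,
        separation=separation,
        fitted=prob,
        n_obs=n,
        auc=model_auc(prob, y),
    )


def _hat_diag(X, w, info, names) -> np.ndarray:
    try:
        info_inv = linalg.inv(info)
    except linalg.LinAlgError:
        raise SingularDesignError(
            f"singular information matrix; collinear columns: "
            f"{_name_collinear(X, names)}"
        )
    return w * np.einsum("ij,jk,ik->i", X, info_inv, X)


def _penalized_ll(y, eta, X, firth: bool) -> float:
    ll = _loglik(y, eta)
    if not firth:
        return ll
    prob = expit(eta)
    w = np.clip(prob * (1.0 - prob), 1e-10, None)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return ll + 0.5 * logdet if sign > 0 else -np.inf


def lr_test(ll_null: float, ll_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested models: statistic and p-value."""
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return stat, float(stats.chi2.sf(stat, df))


def score_test(
    y: np.ndarray, X_base: np.ndarray, fit_base: FitResult, x_new: np.ndarray
) -> tuple[float, float]:
    """Rao score test for adding one column to a fitted base model (1 df).

    Evaluated at the base MLE, so no extended fit is needed.
    """
    y = np.asarray(y, dtype=float).ravel()
    x_new = np.asarray(x_new, dtype=float).ravel()
    prob = fit_base.fitted
    w = np.clip(prob * (1.0 - prob), 1e-10, None)
    u = float(x_new @ (y - prob))
    xtwx = float(x_new @ (w * x_new))
    xtwX = X_base.T @ (w * x_new)
    info = X_base.T @ (X_base * w[:, None])
    v = xtwx - float(xtwX @ linalg.solve(info, xtwX, assume_a="pos"))
    if v <= 0:
        return 0.0, 1.0
    stat = u * u / v
    return stat, float(stats.chi2.sf(stat, 1))


def wald_tests(fit: FitResult, terms: Sequence[str]) -> dict[str, float]:
    p = fit.wald_p()
    return {t: float(p[fit.names.index(t)]) for t in terms}


def model_auc(scores: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Concordance of scores against a binary outcome, tied pairs counted
    one-half (Mann-Whitney). None when only one class is present."""
    y = np.asarray(y, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def cohort_dummies(
    cohorts: pd.Series, reference: Optional[str] = None
) -> tuple[np.ndarray, list[str]]:
    """Indicator columns for cohort, reference level = largest cohort
    (deterministic tie-break by id). Empty when there is a single cohort."""
    counts = cohorts.value_counts()
    if reference is None:
        top = counts.max()
        reference = sorted(c for c in counts.index if counts[c] == top)[0]
    others = [c for c in sorted(counts.index) if c != reference]
    cols = np.column_stack(
        [(cohorts == c).to_numpy(dtype=float) for c in others]
    ) if others else np.empty((len(cohorts), 0))
    return cols, [f"cohort[{c}]" for c in others]


def build_design(
    rows: pd.DataFrame,
    items: Sequence[str],
    cohort_col: Optional[str] = "cohort_id",
    outcome_col: str = "treated",
    cohort_reference: Optional[str] = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Outcome vector and design matrix: intercept, cohort indicators
    (when a cohort column is given), then item columns."""
    y = rows[outcome_col].to_numpy(dtype=float)
    blocks = [np.ones((len(rows), 1))]
    names = ["intercept"]
    if cohort_col is not None and rows[cohort_col].nunique() > 1:
        dummies, dnames = cohort_dummies(rows[cohort_col], cohort_reference)
        blocks.append(dummies)
        names += dnames
    for item in items:
        blocks.append(rows[item].to_numpy(dtype=float)[:, None])
        names.append(item)
    return y, np.hstack(blocks), names


def _drop_constant(rows: pd.DataFrame, items: Sequence[str]) -> list[str]:
    kept = []
    for item in items:
        vals = rows[item].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            warnings.warn(f"dropping constant predictor column {item!r}")
        else:
            kept.append(item)
    return kept


def univariate_item_models(
    rows: pd.DataFrame,
    items: Sequence[str],
    cohort_col: str = "cohort_id",
    firth: bool = False,
) -> pd.DataFrame:
    """One cohort-adjusted model per item: outcome ~ item + cohort.

    Returns the item's odds ratio with 95% Wald CI and p-value; separation
    or non-convergence of one item's model does not affect the others.
    """
    records = []
    for item in _drop_constant(rows, items):
        y, X, names = build_design(rows, [item], cohort_col)
        try:
            fit = fit_logistic(y, X, names, firth=firth)
        except SingularDesignError:
            records.append(
                dict(item=item, odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                     p=np.nan, converged=False, separation=False)
            )
            continue
        tab = fit.odds_ratios().set_index("term").loc[item]
        records.append(
            dict(
                item=item,
                odds_ratio=tab["or"],
                ci_low=tab["or_ci_low"],
                ci_high=tab["or_ci_high"],
                p=tab["p"],
                converged=fit.converged,
                separation=fit.separation,
            )
        )
    return pd.DataFrame.from_records(records)


@dataclass
class StepwiseStep:
    action: str  # "add" | "remove" | "stop"
    item: Optional[str]
    p: Optional[float]
    candidates_tested: dict[str, float] = field(default_factory=dict)


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep]
    selected: list[str]
    p_enter: float
    p_remove: float
    entry_stat: str


def forward_stepwise(
    rows: pd.DataFrame,
    candidates: Sequence[str],
    cohort_col: Optional[str] = "cohort_id",
    outcome_col: str = "treated",
    p_enter: float = 0.10,
    p_remove: float = 0.05,
    entry_stat: str = "lr",
    firth: bool = False,
) -> tuple[StepwiseTrace, FitResult]:
    """Forward stepwise selection with cohort indicators forced in.

    At each step the candidate with the smallest entry p-value (likelihood
    ratio by default, Rao score via ``entry_stat="score"``) joins the model
    if p < ``p_enter`` (ties broken lexicographically); included items whose
    Wald p rises to >= ``p_remove`` are then removed one at a time, worst
    first, refitting in between. Stops when no addition is possible or a
    model state repeats. Candidates whose fit fails (separation, collinear
    with the current model) are skipped for that step with a warning.
    """
    if entry_stat not in ("lr", "score"):
        raise ValueError("entry_stat must be 'lr' or 'score'")
    candidates = _drop_constant(rows, candidates)
    if not candidates:
        raise ValueError("no usable candidate items")
    included: list[str] = []
    steps: list[StepwiseStep] = []
    seen = {frozenset()}

    def fit_items(items: Sequence[str]) -> FitResult:
        y, X, names = build_design(rows, items, cohort_col, outcome_col)
        return fit_logistic(y, X, names, firth=firth)

    current = fit_items(included)
    while True:
        tested: dict[str, float] = {}
        y_base, X_base, _ = build_design(rows, included, cohort_col, outcome_col)
        for cand in candidates:
            if cand in included:
                continue
            try:
                if entry_stat == "lr":
                    fit_ext = fit_items(included + [cand])
                    if not fit_ext.converged and not firth:
                        warnings.warn(f"skipping {cand!r}: entry fit did not converge")
                        continue
                    _, p = lr_test(current.loglik, fit_ext.loglik, 1)
                else:
                    x_new = rows[cand].to_numpy(dtype=float)
                    _, p = score_test(y_base, X_base, current, x_new)
            except SingularDesignError:
                warnings.warn(f"skipping {cand!r}: collinear with current model")
                continue
            tested[cand] = p
        eligible = {c: p for c, p in tested.items() if p < p_enter}
        if not eligible:
            steps.append(StepwiseStep("stop", None, None, tested))
            break
        best_p = min(eligible.values())
        best = sorted(c for c, p in eligible.items() if p == best_p)[0]
        included.append(best)
        steps.append(StepwiseStep("add", best, best_p, tested))
        current = fit_items(included)
        # removal phase: worst Wald p first, one at a time
        while included:
            pvals = wald_tests(current, included)
            worst = max(included, key=lambda t: (pvals[t], t))
            if np.isnan(pvals[worst]) or pvals[worst] < p_remove:
                break
            included.remove(worst)
            steps.append(StepwiseStep("remove", worst, pvals[worst]))
            current = fit_items(included)
        state = frozenset(included)
        if state in seen:
            steps.append(StepwiseStep("stop", None, None))
            break
        seen.add(state)

    trace = StepwiseTrace(
        steps=steps,
        selected=list(included),
        p_enter=p_enter,
        p_remove=p_remove,
        entry_stat=entry_stat,
    )
    return trace, current
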