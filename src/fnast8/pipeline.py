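"""End-to-end pipeline: extract analysis rows (or simulate them), screen
items across cohorts, select items by forward stepwise logistic regression,
calibrate simplified-scale thresholds, and validate on an external cohort.
Every run is reproducible from (config, seed) and writes a machine-readable
summary."""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, io
from .core import (
    ANY_TREMORS,
    MissingAnalysisDayError,
    TREMOR_ITEMS,
    TreatmentRule,
    extract_analysis_row,
)
from .calibration import select_thresholds, validate_external
from .logistic import forward_stepwise, model_auc, univariate_item_models
from .screening import format_p, screen_items
from .simulate import SITE_RULES, default_config, simulate_analysis_frame

__all__ = ["PipelineConfig", "StepwiseOptions", "run_pipeline", "extract_analysis_frame"]

logger = logging.getLogger("fnast8")


class StepwiseOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    entry_stat: Literal["lr", "score"] = "lr"
    p_enter: float = 0.10
    p_remove: float = 0.05
    firth: bool = False
    tremor_mode: Literal["any", "separate"] = "any"


class PipelineConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    source: Literal["simulate", "assessments", "analysis_rows"] = "simulate"
    assessments_path: Optional[str] = None
    analysis_rows_path: Optional[str] = None
    validation_rows_path: Optional[str] = None
    validation_cohort: Optional[str] = "mother"
    #: cohort_id -> named site rule or explicit [[k, threshold], ...]
    site_rules: dict[str, object] = Field(default_factory=dict)
    stepwise: StepwiseOptions = StepwiseOptions()
    heterogeneity_pp: float = 50.0
    out_dir: str = "fnast8_run"
    seed: int = 0
    log_level: str = "INFO"


def _rule_for(cfg: PipelineConfig, cohort_id: str) -> TreatmentRule:
    spec = cfg.site_rules.get(cohort_id, "kentucky_sites")
    clauses = SITE_RULES[spec] if isinstance(spec, str) else tuple(
        (int(k), int(t)) for k, t in spec
    )
    return TreatmentRule(clauses=tuple(clauses))


def extract_analysis_frame(records, cfg: PipelineConfig) -> pd.DataFrame:
    """Group assessments by neonate and extract one analysis row each;
    neonates lacking an assessment on their analysis day are dropped with a
    logged count."""
    by_neonate: dict[tuple[str, str], list] = defaultdict(list)
    for rec in records:
        by_neonate[(rec.neonate_id, rec.cohort_id)].append(rec)
    rows, dropped = [], 0
    for (nid, cid), recs in by_neonate.items():
        try:
            rows.append(extract_analysis_row(nid, cid, recs, _rule_for(cfg, cid)))
        except MissingAnalysisDayError as exc:
            dropped += 1
            logger.warning("dropped neonate: %s", exc)
    if dropped:
        logger.info("dropped %d neonates with no assessment on the analysis day", dropped)
    return io.analysis_rows_to_frame(rows)


def _screening_report(results) -> pd.DataFrame:
    recs = []
    for r in results:
        entry = {"item_id": r.item_id}
        for cohort, (e, t) in r.counts.items():
            entry[f"endorsed[{cohort}]"] = e
            entry[f"rate[{cohort}]"] = e / t
        entry.update(
            chi2_stat=r.chi2_stat,
            chi2_df=r.chi2_df,
            chi2_p=r.chi2_p,
            chi2_p_display=format_p(r.chi2_p),
            max_pp_difference=r.max_pp_difference,
            auc=r.auc,
            auc_ci_low=None if r.auc_ci is None else r.auc_ci[0],
            auc_ci_high=None if r.auc_ci is None else r.auc_ci[1],
            excluded=r.excluded,
            exclusion_reason=r.exclusion_reason,
            zero_variance=r.zero_variance,
        )
        recs.append(entry)
    return pd.DataFrame(recs)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute extract -> screen -> stepwise -> calibrate -> validate and
    write all stage reports under the run directory. Returns that path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    log_lines = [
        f"fnast8 {__version__}",
        f"seed {cfg.seed}",
        f"config_sha256 {hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()}",
        f"config {cfg.model_dump_json()}",
    ]
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        summary = _run_stages(cfg, out, log_lines)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        (out / "run.log").write_text("\n".join(log_lines) + f"\nFAILED: {exc}\n")
        raise
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _run_stages(cfg: PipelineConfig, out: Path, log_lines: list[str]) -> dict:
    validation_frame = None
    if cfg.source == "simulate":
        sim = default_config(seed=cfg.seed)
        frame_all, truth = simulate_analysis_frame(sim)
        io.write_truth_log(truth, out / "truth.jsonl")
        is_val = frame_all["cohort_id"] == cfg.validation_cohort
        frame = frame_all[~is_val].reset_index(drop=True)
        if is_val.any():
            validation_frame = frame_all[is_val].reset_index(drop=True)
    elif cfg.source == "assessments":
        records = io.read_assessments(cfg.assessments_path)
        frame = extract_analysis_frame(records, cfg)
    else:
        frame = io.read_analysis_rows(cfg.analysis_rows_path)
    if validation_frame is None and cfg.validation_rows_path:
        validation_frame = io.read_analysis_rows(cfg.validation_rows_path)

    io.write_analysis_rows(frame, out / "analysis_rows.csv")
    log_lines.append(f"analysis rows: {len(frame)}")

    # stage: cross-cohort screening
    results, survivors = screen_items(frame, pp_threshold=cfg.heterogeneity_pp)
    report = _screening_report(results)
    report.to_csv(out / "screening.csv", index=False)
    excluded = {
        r.item_id: r.exclusion_reason for r in results if r.excluded
    }
    zero_var = [r.item_id for r in results if r.zero_variance]
    log_lines.append(f"screen: excluded {excluded}; zero-variance {zero_var}")

    # stage: stepwise selection (cohort forced in)
    sw = cfg.stepwise
    candidates = [i for i in survivors if i not in zero_var]
    work = frame
    if sw.tremor_mode == "any" and all(t in candidates for t in TREMOR_ITEMS):
        work = io.add_any_tremors(frame)
        candidates = [c for c in candidates if c not in TREMOR_ITEMS]
        candidates.append(ANY_TREMORS)
    univariate = univariate_item_models(work, candidates)
    univariate.to_csv(out / "univariate.csv", index=False)
    trace, fit = forward_stepwise(
        work,
        candidates,
        p_enter=sw.p_enter,
        p_remove=sw.p_remove,
        entry_stat=sw.entry_stat,
        firth=sw.firth,
    )
    # reference discrimination: model with every screened candidate
    from .logistic import build_design, fit_logistic

    y_all, X_all, names_all = build_design(work, candidates)
    try:
        full_fit_auc = fit_logistic(y_all, X_all, names_all).auc
    except Exception:  # collinear or separated full model: report nothing
        full_fit_auc = None
    model_report = {
        "selected_items": trace.selected,
        "entry_stat": trace.entry_stat,
        "p_enter": trace.p_enter,
        "p_remove": trace.p_remove,
        "steps": [
            {"action": s.action, "item": s.item, "p": s.p} for s in trace.steps
        ],
        "coefficients": fit.odds_ratios().to_dict(orient="records"),
        "auc": fit.auc,
        "auc_all_candidates": full_fit_auc,
        "converged": fit.converged,
    }
    (out / "model.json").write_text(json.dumps(model_report, indent=2))
    log_lines.append(f"selected: {trace.selected} (AUC {fit.auc})")

    # stage: threshold calibration of the selected-item unit-weight score
    from .calibration import DegenerateTableError

    simplified = _selected_score(work, trace.selected)
    try:
        calib = select_thresholds(frame["original_score"].to_numpy(), simplified)
    except DegenerateTableError as exc:
        calib = None
        log_lines.append(f"calibration stage degenerate, skipped: {exc}")
    if calib is not None:
        pd.DataFrame(
            calib.crosstab,
            index=["orig_low", "orig_medium", "orig_high"],
            columns=["simp_low", "simp_medium", "simp_high"],
        ).to_csv(out / "crosstab.csv")
        calib.grid.to_csv(out / "kappa_grid.csv", index=False)

    # stage: external validation
    validation = None
    if validation_frame is not None and len(validation_frame) and trace.selected:
        vwork = (
            io.add_any_tremors(validation_frame)
            if ANY_TREMORS in trace.selected
            else validation_frame
        )
        from .logistic import SingularDesignError

        try:
            auc, ci, _ = validate_external(trace.selected, vwork)
            validation = {"auc": auc, "auc_ci": ci, "n": int(len(validation_frame))}
            log_lines.append(f"validation AUC: {auc}")
        except SingularDesignError as exc:
            validation = {"auc": None, "auc_ci": None,
                          "n": int(len(validation_frame)), "error": str(exc)}
            log_lines.append(f"validation stage failed (collinear items): {exc}")
    else:
        log_lines.append("validation stage skipped: no validation cohort")

    return {
        "seed": cfg.seed,
        "n_rows": int(len(frame)),
        "excluded_items": excluded,
        "zero_variance_items": zero_var,
        "selected_items": trace.selected,
        "model_auc": fit.auc,
        "auc_all_candidates": full_fit_auc,
        "thresholds": None if calib is None else list(calib.thresholds),
        "kappa": None if calib is None else calib.kappa,
        "kappa_ci": None if calib is None else list(calib.kappa_ci),
        "validation": validation,
    }


def _selected_score(frame: pd.DataFrame, selected: list[str]) -> np.ndarray:
    total = np.zeros(len(frame), dtype=np.int64)
    for item in selected:
        total += frame[item].astype(int).to_numpy()
    return total
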