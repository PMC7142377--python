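# fnast8

Derivation and validation of a simplified 8-item neonatal abstinence
severity scale from the 21-item Finnegan Neonatal Abstinence Scoring Tool
(FNAST), implemented as a tested, reusable pipeline:

1. **Scoring & extraction** (`fnast8.core`) — the 21 graded items with
   their printed integer weights, present/absent dichotomization into 21
   binary signs, the unit-weight 8-item simplified score (0–8), severity
   categories, site-specific consecutive-score treatment-initiation rules,
   and extraction of each neonate's single analysis point (highest-scoring
   assessment on the first treatment day, or day 3 of life if never
   treated).
2. **Cross-cohort screening** (`fnast8.screening`) — per-item Pearson χ²
   homogeneity tests, endorsement-concordance AUCs with Hanley–McNeil
   intervals, and the exclusion filter (never-observed signs, and signs
   whose cohort endorsement rates differ by more than 50 percentage
   points).
3. **Item selection** (`fnast8.logistic`) — logistic regression by IRLS
   with step-halving, separation guard, and optional Firth penalization,
   implemented from first principles; forward stepwise selection with
   cohort indicators forced in (entry by likelihood-ratio or Rao score
   test at p < .10, Wald removal at p ≥ .05).
4. **Threshold calibration** (`fnast8.calibration`) — linear-weighted
   Cohen's kappa over an exhaustive cutpoint grid to align the simplified
   scale's low/medium/high categories with the original scale's
   predetermined 8/12 cutoffs, plus refit-and-discriminate validation on
   an external cohort.
5. **Synthetic cohorts** (`fnast8.simulate`) — a latent-severity
   multi-cohort generator whose per-cohort endorsement rates are
   moment-matched to the published summary tables and whose treatment
   labels arise from the configured consecutive-score rules, so every
   downstream stage is testable without patient-level data. Also builds
   deterministic fixture tables reproducing the published marginal counts.
6. **Orchestration** (`fnast8.pipeline`, `fnast8.cli`, `fnast8.io`) —
   strict CSV/JSON I/O, a validated pipeline configuration, and a CLI.

No patient-level data from the source study were deposited; the packaged
JSON resources under `src/fnast8/data/` carry only its printed summary
tables (item weights, per-cohort endorsement counts, the category
crosstab), which several statistics can be recomputed from exactly.

## CLI

```sh
fnast8 simulate --seed 2 --out rows.csv          # synthetic analysis rows
fnast8 score assessments.csv --out rows.csv      # extract analysis points
fnast8 screen rows.csv --out screening.csv       # cross-cohort screening
fnast8 select rows.csv --out model.json          # stepwise selection
fnast8 calibrate rows.csv --out calibration.json # threshold calibration
fnast8 run-all --seed 2 --out-dir run/           # full pipeline
```

`run-all` writes `analysis_rows.csv`, `screening.csv`, `univariate.csv`,
`model.json`, `crosstab.csv`, `kappa_grid.csv`, `truth.jsonl`,
`summary.json`, and `run.log` into the run directory; re-running with the
same config and seed reproduces the outputs byte for byte. A JSON config
file (validated, unknown keys rejected) can be passed via `--config`.

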