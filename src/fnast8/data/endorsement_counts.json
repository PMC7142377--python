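{
  "schema_version": 1,
  "description": "Published per-cohort endorsement counts of the dichotomized scale items at each neonate's analysis point: three derivation cohorts plus the external validation cohort. Counts are numbers of neonates with the sign present.",
  "cohort_sizes": {
    "louisville": 127,
    "tufts": 203,
    "kentucky": 94,
    "mother": 109
  },
  "derivation_cohorts": ["louisville", "tufts", "kentucky"],
  "validation_cohort": "mother",
  "counts": {
    "high_pitched_crying":     {"louisville": 98,  "tufts": 42,  "kentucky": 75, "mother": 31},
    "sleeps_lt_3h":            {"louisville": 70,  "tufts": 108, "kentucky": 80, "mother": 82},
    "hyperactive_moro":        {"louisville": 36,  "tufts": 35,  "kentucky": 64, "mother": 42},
    "tremors_disturbed":       {"louisville": 119, "tufts": 163, "kentucky": 64, "mother": 85},
    "tremors_undisturbed":     {"louisville": 60,  "tufts": 67,  "kentucky": 19, "mother": 41},
    "increased_muscle_tone":   {"louisville": 120, "tufts": 182, "kentucky": 87, "mother": 99},
    "excoriation":             {"louisville": 36,  "tufts": 48,  "kentucky": 20, "mother": 21},
    "myoclonic_jerks":         {"louisville": 5,   "tufts": 3,   "kentucky": 5,  "mother": 1},
    "sweating":                {"louisville": 8,   "tufts": 10,  "kentucky": 8,  "mother": 6},
    "temp_ge_37_2":            {"louisville": 30,  "tufts": 81,  "kentucky": 18, "mother": 1},
    "yawning":                 {"louisville": 4,   "tufts": 14,  "kentucky": 3,  "mother": 4},
    "mottling":                {"louisville": 55,  "tufts": 50,  "kentucky": 19, "mother": 13},
    "nasal_stuffiness":        {"louisville": 25,  "tufts": 21,  "kentucky": 13, "mother": 13},
    "sneezing":                {"louisville": 40,  "tufts": 67,  "kentucky": 41, "mother": 34},
    "nasal_flaring":           {"louisville": 4,   "tufts": 5,   "kentucky": 8,  "mother": 3},
    "resp_gt_60":              {"louisville": 57,  "tufts": 60,  "kentucky": 41, "mother": 53},
    "excessive_sucking":       {"louisville": 72,  "tufts": 63,  "kentucky": 61, "mother": 29},
    "poor_feeding":            {"louisville": 33,  "tufts": 35,  "kentucky": 32, "mother": 31},
    "regurgitation":           {"louisville": 25,  "tufts": 24,  "kentucky": 27, "mother": 19},
    "loose_watery_stools":     {"louisville": 32,  "tufts": 34,  "kentucky": 38, "mother": 28},
    "generalized_convulsions": {"louisville": 0,   "tufts": 0,   "kentucky": 0,  "mother": 0}
  },
  "treated_total": 238,
  "n_derivation_total": 424
}
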