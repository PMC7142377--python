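{
  "schema_version": 1,
  "description": "The 21 graded items of the Finnegan Neonatal Abstinence Scoring Tool: ordered severity levels with integer weights, and the binary sign each item collapses to under present/absent dichotomization.",
  "items": [
    {
      "item_id": "high_pitched_crying",
      "label": "High-pitched crying",
      "levels": [["excessive", 2], ["continuous", 3]],
      "binary_group": "high_pitched_crying"
    },
    {
      "item_id": "sleeps_after_feeding",
      "label": "Sleeps after feeding",
      "levels": [["lt_3h", 1], ["lt_2h", 2], ["lt_1h", 3]],
      "binary_group": "sleeps_lt_3h"
    },
    {
      "item_id": "moro_reflex",
      "label": "Moro reflex",
      "levels": [["hyperactive", 2], ["markedly_hyperactive", 3]],
      "binary_group": "hyperactive_moro"
    },
    {
      "item_id": "tremors_disturbed",
      "label": "Tremors when disturbed",
      "levels": [["mild", 1], ["moderate_severe", 2]],
      "binary_group": "tremors_disturbed"
    },
    {
      "item_id": "tremors_undisturbed",
      "label": "Tremors when undisturbed",
      "levels": [["mild", 3], ["moderate_severe", 4]],
      "binary_group": "tremors_undisturbed"
    },
    {
      "item_id": "increased_muscle_tone",
      "label": "Increased muscle tone",
      "levels": [["present", 2]],
      "binary_group": "increased_muscle_tone"
    },
    {
      "item_id": "excoriation",
      "label": "Excoriation",
      "levels": [["present", 1]],
      "binary_group": "excoriation"
    },
    {
      "item_id": "myoclonic_jerks",
      "label": "Myoclonic jerks",
      "levels": [["present", 3]],
      "binary_group": "myoclonic_jerks"
    },
    {
      "item_id": "generalized_convulsions",
      "label": "Generalized convulsions",
      "levels": [["present", 5]],
      "binary_group": "generalized_convulsions"
    },
    {
      "item_id": "sweating",
      "label": "Sweating",
      "levels": [["present", 1]],
      "binary_group": "sweating"
    },
    {
      "item_id": "body_temperature",
      "label": "Body temperature",
      "levels": [["c_37_2_to_38_3", 1], ["ge_38_4", 2]],
      "binary_group": "temp_ge_37_2"
    },
    {
      "item_id": "yawning",
      "label": "Yawning >3 times/scoring interval",
      "levels": [["present", 1]],
      "binary_group": "yawning"
    },
    {
      "item_id": "mottling",
      "label": "Mottling",
      "levels": [["present", 1]],
      "binary_group": "mottling"
    },
    {
      "item_id": "nasal_stuffiness",
      "label": "Nasal stuffiness",
      "levels": [["present", 1]],
      "binary_group": "nasal_stuffiness"
    },
    {
      "item_id": "sneezing",
      "label": "Sneezing >3 times/scoring interval",
      "levels": [["present", 1]],
      "binary_group": "sneezing"
    },
    {
      "item_id": "nasal_flaring",
      "label": "Nasal flaring",
      "levels": [["present", 2]],
      "binary_group": "nasal_flaring"
    },
    {
      "item_id": "respiratory_rate",
      "label": "Respiratory rate",
      "levels": [["gt_60", 1], ["gt_60_with_retractions", 2]],
      "binary_group": "resp_gt_60"
    },
    {
      "item_id": "excessive_sucking",
      "label": "Excessive sucking",
      "levels": [["present", 1]],
      "binary_group": "excessive_sucking"
    },
    {
      "item_id": "poor_feeding",
      "label": "Poor feeding",
      "levels": [["present", 2]],
      "binary_group": "poor_feeding"
    },
    {
      "item_id": "vomiting",
      "label": "Vomiting",
      "levels": [["regurgitation", 2], ["projectile", 3]],
      "binary_group": "regurgitation"
    },
    {
      "item_id": "stools",
      "label": "Stools",
      "levels": [["loose", 2], ["watery", 3]],
      "binary_group": "loose_watery_stools"
    }
  ]
}
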