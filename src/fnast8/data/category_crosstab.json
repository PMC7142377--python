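{
  "schema_version": 1,
  "description": "Published 3x3 contingency table of original-scale severity categories (rows: score 0-7, 8-11, >=12) against simplified-scale categories (columns: score 0-3, 4, >=5) among the 424 derivation neonates.",
  "row_categories": ["low", "medium", "high"],
  "col_categories": ["low", "medium", "high"],
  "original_cutpoints": [8, 12],
  "simplified_cutpoints": [4, 5],
  "counts": [
    [87, 13, 2],
    [47, 58, 23],
    [25, 41, 128]
  ]
}
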