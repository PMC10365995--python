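{
  "_comment": "Invented default manipulation recipes: plausible starting points for transforming a glazed-ceramic source stimulus into each target material. Every value is an editable default, not a calibrated constant. The velvet recipe requires a per-scene highlight direction nm (see velvet_nm).",
  "recipes": {
    "gold": {"b": 0.5, "s_col": [1.0, 0.72, 0.2], "d_col": [0.0, 0.0, 0.0], "s_boost": 1.6, "s_sat": 1.2},
    "silver": {"b": 0.3, "s_col": [0.95, 0.97, 1.0], "d_col": [0.0, 0.0, 0.0], "s_boost": 1.8},
    "brown_metal": {"b": 0.8, "s_col": [0.85, 0.5, 0.25], "d_col": [0.0, 0.0, 0.0], "s_boost": 1.4, "s_sat": 1.3},
    "solid_chocolate": {"b": 1.5, "s_col": [1.0, 1.0, 1.0], "d_col": [0.45, 0.22, 0.08], "s_boost": 0.5, "d_boost": 1.2},
    "melted_chocolate": {"b": 0.6, "s_col": [1.0, 0.95, 0.9], "d_col": [0.45, 0.22, 0.08], "s_boost": 0.9, "d_boost": 1.1},
    "glazed_porcelain": {"b": 0.2, "d_boost": 2.2, "d_sat": 0.3, "s_boost": 1.1},
    "unglazed_porcelain": {"b": 3.5, "s_boost": 0.35, "d_boost": 2.4, "d_sat": 0.2},
    "pearl": {"b": 2.0, "s_boost": 0.8, "s_sat": 1.4, "d_boost": 1.8, "d_gamma": 0.8, "d_sat": 1.3},
    "plastic": {"b": 0.9, "s_boost": 1.0, "d_boost": 1.3, "d_sat": 1.5},
    "rubber": {"b": 2.8, "s_boost": 0.45, "d_boost": 0.8},
    "wax": {"b": 2.2, "s_boost": 0.6, "d_boost": 1.6, "d_gamma": 0.85, "d_sat": 1.4},
    "velvet": {"b": 3.0, "s_boost": 1.5, "velvet": true}
  },
  "velvet_nm": {
    "bunny|campus": [0.57, -0.53, 0.63],
    "bunny|kitchen": [-0.22, -0.48, 0.85],
    "dragon|campus": [-0.62, 0.7, 0.35],
    "dragon|kitchen": [-0.72, 0.57, 0.39]
  }
}
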