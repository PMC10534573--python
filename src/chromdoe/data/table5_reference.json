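{
  "description": "Published validation parameters (reference metadata for report rendering and acceptance-band checks; the raw instrument signals behind them are not available, so these are not recomputation targets).",
  "substances": {
    "ziprasidone": {"class": "active",   "lod_ug_ml": null, "range_ug_ml": [25.0, 75.0], "slope": 0.7832,  "intercept": -0.032,  "r": 0.9999,
      "recovery": {"40": [98.65, 0.76], "50": [98.56, 0.88], "60": [98.57, 0.34]}},
    "impurity_I":  {"class": "impurity", "lod_ug_ml": 0.15, "range_ug_ml": [0.5, 1.2],   "slope": 1.0216,  "intercept": 0.0945,  "r": 0.9989,
      "recovery": {"0.5": [97.01, 0.61], "1.0": [102.80, 0.24], "1.2": [105.90, 0.16]}},
    "impurity_II": {"class": "impurity", "lod_ug_ml": 0.15, "range_ug_ml": [0.5, 1.2],   "slope": 0.6459,  "intercept": 0.0167,  "r": 0.9965,
      "recovery": {"0.5": [105.37, 0.78], "1.0": [93.77, 3.99], "1.2": [95.77, 0.13]}},
    "impurity_III": {"class": "impurity", "lod_ug_ml": 0.15, "range_ug_ml": [0.5, 1.2],  "slope": 0.82092, "intercept": 0.0675,  "r": 0.9989,
      "recovery": {"0.5": [97.82, 0.66], "1.0": [99.36, 0.39], "1.2": [104.65, 1.24]}},
    "impurity_IV": {"class": "impurity", "lod_ug_ml": 0.15, "range_ug_ml": [0.5, 1.2],   "slope": 0.3345,  "intercept": -0.0313, "r": 0.9958,
      "recovery": {"0.5": [107.57, 3.26], "1.0": [98.42, 2.90], "1.2": [106.35, 8.15]}},
    "impurity_V":  {"class": "impurity", "lod_ug_ml": 0.15, "range_ug_ml": [0.5, 1.2],   "slope": 1.5028,  "intercept": 0.0173,  "r": 0.9949,
      "recovery": {"0.5": [101.95, 1.06], "1.0": [85.69, 1.07], "1.2": [89.02, 0.31]}}
  },
  "precision_rsd": {"ziprasidone": 0.40, "impurity_I": 3.85, "impurity_II": 5.80, "impurity_III": 3.17, "impurity_IV": 6.25, "impurity_V": 8.10}
}
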