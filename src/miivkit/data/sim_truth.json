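{
  "note": "Population values of the five-factor study design: two correlated exogenous and three endogenous latent variables in a recursive standardized structural model, three indicators per factor with standardized loadings 0.8/0.65/0.5, ordinal indicators for eta2 and eta4 thresholded to five categories.",
  "exogenous_correlation": 0.3,
  "structural": {
    "eta3": {"eta1": 0.4, "eta2": 0.4},
    "eta4": {"eta1": 0.25, "eta2": 0.25, "eta3": 0.35},
    "eta5": {"eta1": 0.2, "eta2": 0.2, "eta3": 0.25, "eta4": 0.25}
  },
  "loadings": [0.8, 0.65, 0.5],
  "ordinal_factors": ["eta2", "eta4"],
  "category_probabilities": [0.04, 0.05, 0.21, 0.46, 0.24]
}
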