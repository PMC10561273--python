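{
  "version": 1,
  "description": "Published coefficient sets for the intrathecal dispersion correlations: DD10 linear guideline, caudocranial-velocity lines, log-log dispersion law with quadratic frequency offset, and the dimensionless (Pe, Womersley) form.",
  "dd10": {"a": -1.4150, "b": 2.8786, "c": 19.8668, "r_squared": 0.7916},
  "ccv_f": {"intercept": 0.3014, "slope": 0.0012},
  "ccv_u": {"intercept": 0.3752, "slope": 0.0012},
  "logD": {"kappa": 0.7419, "a0": -1.0386, "a1": 0.0055, "a2": -5.8858e-05, "r_squared": 0.9273},
  "dimless": {"K": 0.74, "phi0": 2.4786, "phi1": 0.3130, "phi2": -0.0229, "r_squared": 0.9278},
  "headline": {
    "dexp_range_sv05_cm2_min": [1.50, 2.94],
    "dexp_range_sv10_cm2_min": [2.57, 4.70],
    "repeatability_sd_cm2_min": 0.29
  }
}
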