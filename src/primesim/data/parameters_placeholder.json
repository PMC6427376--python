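{
  "meta": {
    "schema_version": 1,
    "provenance": "placeholder",
    "description": "Editable dose-response parameter file. Every record is a PLACEHOLDER: magnitudes are literature-plausible but are not the meta-analysis values behind any published national estimate. Replace rr_per_increment / increment / cap_level / ln_rr_se (and the mediation slopes) with sourced meta-analysis values before interpreting absolute outputs.",
    "units": {
      "systolic_bp": "mmHg",
      "serum_cholesterol": "mmol/L",
      "bmi": "kg/m^2"
    }
  },
  "relative_risks": [
    {"exposure": "fruits", "cause": "chd", "rr_per_increment": 0.93, "increment": 100.0, "reference_level": 0.0, "cap_level": 400.0, "ln_rr_se": 0.02, "provenance": "placeholder"},
    {"exposure": "fruits", "cause": "stroke", "rr_per_increment": 0.89, "increment": 100.0, "reference_level": 0.0, "cap_level": 400.0, "ln_rr_se": 0.03, "provenance": "placeholder"},
    {"exposure": "fruits", "cause": "lung_cancer", "rr_per_increment": 0.95, "increment": 100.0, "reference_level": 0.0, "cap_level": 300.0, "ln_rr_se": 0.03, "provenance": "placeholder"},
    {"exposure": "vegetables", "cause": "chd", "rr_per_increment": 0.95, "increment": 100.0, "reference_level": 0.0, "cap_level": 400.0, "ln_rr_se": 0.02, "provenance": "placeholder"},
    {"exposure": "vegetables", "cause": "stroke", "rr_per_increment": 0.94, "increment": 100.0, "reference_level": 0.0, "cap_level": 400.0, "ln_rr_se": 0.03, "provenance": "placeholder"},
    {"exposure": "vegetables", "cause": "lung_cancer", "rr_per_increment": 0.96, "increment": 100.0, "reference_level": 0.0, "cap_level": 300.0, "ln_rr_se": 0.03, "provenance": "placeholder"},
    {"exposure": "fiber", "cause": "chd", "rr_per_increment": 0.91, "increment": 10.0, "reference_level": 0.0, "cap_level": 35.0, "ln_rr_se": 0.03, "provenance": "placeholder"},
    {"exposure": "fiber", "cause": "stroke", "rr_per_increment": 0.93, "increment": 10.0, "reference_level": 0.0, "cap_level": 35.0, "ln_rr_se": 0.04, "provenance": "placeholder"},
    {"exposure": "fiber", "cause": "colorectal_cancer", "rr_per_increment": 0.90, "increment": 10.0, "reference_level": 0.0, "cap_level": 35.0, "ln_rr_se": 0.04, "provenance": "placeholder"},
    {"exposure": "systolic_bp", "cause": "chd", "rr_per_increment": 1.25, "increment": 10.0, "reference_level": 0.0, "cap_level": null, "ln_rr_se": 0.03, "provenance": "placeholder"},
    {"exposure": "systolic_bp", "cause": "stroke", "rr_per_increment": 1.40, "increment": 10.0, "reference_level": 0.0, "cap_level": null, "ln_rr_se": 0.04, "provenance": "placeholder"},
    {"exposure": "systolic_bp", "cause": "heart_failure", "rr_per_increment": 1.30, "increment": 10.0, "reference_level": 0.0, "cap_level": null, "ln_rr_se": 0.06, "provenance": "placeholder"},
    {"exposure": "systolic_bp", "cause": "hypertensive", "rr_per_increment": 1.60, "increment": 10.0, "reference_level": 0.0, "cap_level": null, "ln_rr_se": 0.08, "provenance": "placeholder"},
    {"exposure": "serum_cholesterol", "cause": "chd", "rr_per_increment": 1.35, "increment": 1.0, "reference_level": 0.0, "cap_level": null, "ln_rr_se": 0.05, "provenance": "placeholder"}
  ],
  "mediation": [
    {"source": "salt", "mediator": "systolic_bp", "slope": 1.0, "slope_se": 0.2, "provenance": "placeholder"},
    {"source": "saturated_fat", "mediator": "serum_cholesterol", "slope": 0.05, "slope_se": 0.01, "provenance": "placeholder"},
    {"source": "pufa", "mediator": "serum_cholesterol", "slope": -0.03, "slope_se": 0.008, "provenance": "placeholder"},
    {"source": "mufa", "mediator": "serum_cholesterol", "slope": -0.01, "slope_se": 0.005, "provenance": "placeholder"},
    {"source": "cholesterol", "mediator": "serum_cholesterol", "slope": 0.0006, "slope_se": 0.0002, "provenance": "placeholder"},
    {"source": "energy", "mediator": "bmi", "slope": 0.003, "slope_se": 0.001, "provenance": "placeholder"}
  ],
  "jshape": [
    {"cause": "chd", "nadir": 22.5, "curvature_below": 0.0015, "curvature_above": 0.0035},
    {"cause": "stroke", "nadir": 22.5, "curvature_below": 0.001, "curvature_above": 0.003}
  ]
}
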