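{
  "categories": ["mild", "moderate", "severe", "normal"],
  "rater_pairs": [
    {
      "fixture_id": "kappa1_marginals",
      "rater_a": "attending_clinician",
      "rater_b": "pediatric_sonographer",
      "row_marginals": [76, 27, 3, 0],
      "col_marginals": [68, 26, 3, 9],
      "n": 106,
      "diagonal_total": 96,
      "printed_observed_agreement_pct": 90.6,
      "printed_expected_agreement_pct": 52.3,
      "printed_kappa": 0.8,
      "printed_se0": 0.0765,
      "printed_z": 10.19,
      "z_discrepant": true
    },
    {
      "fixture_id": "kappa2_marginals",
      "rater_a": "pediatric_sonographer",
      "rater_b": "radiologist_sonographer",
      "row_marginals": [68, 26, 3, 9],
      "col_marginals": [65, 26, 3, 12],
      "n": 106,
      "diagonal_total": 95,
      "printed_observed_agreement_pct": 89.6,
      "printed_expected_agreement_pct": 46.4,
      "printed_kappa": 0.8,
      "printed_se0": 0.07,
      "printed_z": 11.33,
      "z_discrepant": false
    }
  ],
  "oxygen_2x2": {
    "fixture_id": "oxygen_2x2",
    "tp": 28,
    "fp": 1,
    "fn": 1,
    "tn": 76,
    "printed_sensitivity_pct": 96.6,
    "printed_specificity_pct": 98.7,
    "printed_ppv_pct": 96.6,
    "printed_npv_pct": 98.7,
    "printed_specificity_ci_pct": [93.0, 99.8],
    "printed_sensitivity_ci_pct": [82.2, 99.4]
  }
}
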