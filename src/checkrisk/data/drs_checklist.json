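{
  "name": "Durham Risk Score",
  "version": "1.0",
  "missing_policy": "absent_as_zero",
  "items": [
    {"id": "attempt_lifetime", "label": "Suicide attempt (lifetime)", "weight": 2},
    {"id": "hosp_past_year", "label": "Psychiatric hospitalization (past year)", "weight": 1},
    {"id": "hosp_lifetime", "label": "Psychiatric hospitalization (lifetime)", "weight": 2},
    {"id": "nssi_lifetime", "label": "Nonsuicidal self-injury (lifetime)", "weight": 2},
    {"id": "ideation_past_year", "label": "Suicidal ideation (past year)", "weight": 1},
    {"id": "ideation_lifetime", "label": "Suicidal ideation (lifetime)", "weight": 1},
    {"id": "bpd_lifetime", "label": "Borderline personality disorder (lifetime)", "weight": 2},
    {"id": "unemployed", "label": "Unemployed", "weight": 1},
    {"id": "poor_health", "label": "Poor perceived health", "weight": 1},
    {"id": "lower_income", "label": "Lower income", "weight": 1},
    {"id": "child_physical_abuse", "label": "Child physical abuse (lifetime)", "weight": 1},
    {"id": "sexual_abuse", "label": "Sexual abuse/assault (lifetime)", "weight": 1},
    {"id": "sleep_problems", "label": "Severe sleep problems (past year)", "weight": 1},
    {"id": "ptsd_past_year", "label": "PTSD (past year)", "weight": 1},
    {"id": "mood_disorder", "label": "Mood disorder (lifetime)", "weight": 1},
    {"id": "violence_incarceration", "label": "Violence/incarceration (lifetime)", "weight": 1},
    {"id": "weekly_binges", "label": "Weekly binges (past year)", "weight": 1},
    {"id": "current_smoker", "label": "Current smoker", "weight": 1},
    {"id": "sud_past_year", "label": "Substance use disorder (past year)", "weight": 1},
    {"id": "under_35", "label": "Younger than 35", "weight": 1},
    {"id": "less_than_hs", "label": "Less than high-school education", "weight": 1},
    {"id": "sexual_minority", "label": "Sexual minority", "weight": 1},
    {"id": "female_sex", "label": "Female sex at birth", "weight": 1}
  ],
  "bands": [
    {"name": "Lowest risk", "lower": 0, "upper": 2},
    {"name": "Low risk", "lower": 3, "upper": 5},
    {"name": "Moderate risk", "lower": 6, "upper": 8},
    {"name": "High risk", "lower": 9, "upper": 11},
    {"name": "Very high risk", "lower": 12, "upper": 14},
    {"name": "Highest risk", "lower": 15, "upper": null}
  ]
}
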