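{
  "name": "SAD PERSONS",
  "version": "1983",
  "missing_policy": "absent_as_zero",
  "items": [
    {"id": "male_sex", "label": "Sex (male)", "weight": 1},
    {"id": "age_risk", "label": "Age (<19 or >45)", "weight": 1},
    {"id": "depression", "label": "Depression", "weight": 1},
    {"id": "previous_attempt", "label": "Previous attempt", "weight": 1},
    {"id": "ethanol_abuse", "label": "Ethanol abuse", "weight": 1},
    {"id": "rational_thinking_loss", "label": "Rational thinking loss", "weight": 1},
    {"id": "social_supports_lacking", "label": "Social supports lacking", "weight": 1},
    {"id": "organized_plan", "label": "Organized plan", "weight": 1},
    {"id": "no_spouse", "label": "No spouse", "weight": 1},
    {"id": "sickness", "label": "Sickness", "weight": 1}
  ],
  "bands": [
    {"name": "Low risk", "lower": 0, "upper": 4},
    {"name": "Medium risk", "lower": 5, "upper": 6},
    {"name": "High risk", "lower": 7, "upper": null}
  ]
}
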