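{
  "description": "Published risk-group and cut-score count tables for the combined development (N=17,630) and validation (N=18,024) cohorts of the 23-item checklist study.",
  "bands": ["Lowest risk", "Low risk", "Moderate risk", "High risk", "Very high risk", "Highest risk"],
  "band_ranges": ["0-2", "3-5", "6-8", "9-11", "12-14", "15+"],
  "development": {
    "controls": [8055, 7095, 1630, 507, 141, 73],
    "attempters": [2, 24, 34, 28, 21, 20],
    "total": 17630
  },
  "validation": {
    "controls": [7844, 7332, 1845, 600, 176, 68],
    "attempters": [2, 24, 36, 41, 24, 32],
    "total": 18024
  },
  "cut6": {
    "development": {"below_controls": 15150, "below_attempts": 26, "above_controls": 2351, "above_attempts": 103},
    "validation": {"below_controls": 15176, "below_attempts": 26, "above_controls": 2689, "above_attempts": 133}
  }
}
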