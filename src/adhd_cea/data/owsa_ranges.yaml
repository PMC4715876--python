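# Default one-way sensitivity ranges (+/-25% around base-case values unless a
# natural bound applies). The published tornado's exact bounds are not part of
# the input tables; these ranges exercise the same parameter families.
- {path: utilities.Normal, low: 0.62925, high: 1.0}
- {path: utilities.Mild, low: 0.59025, high: 0.98375}
- {path: utilities.Moderate, low: 0.4335, high: 0.7225}
- {path: utilities.Severe, low: 0.333, high: 0.555}
- {path: costs.weekly_medical.Normal, low: 3.5325, high: 5.8875}
- {path: costs.weekly_medical.Mild, low: 3.57, high: 5.95}
- {path: costs.weekly_medical.Moderate, low: 10.2225, high: 17.0375}
- {path: costs.weekly_medical.Severe, low: 21.285, high: 35.475}
- {path: costs.weekly_productivity.Normal, low: 10.95, high: 18.25}
- {path: costs.weekly_productivity.Mild, low: 11.535, high: 19.225}
- {path: costs.weekly_productivity.Moderate, low: 45.225, high: 125.10}
- {path: costs.weekly_productivity.Severe, low: 93.825, high: 156.375}
- {path: arms.intervention.drug_daily, low: 5.0175, high: 8.3625}
- {path: arms.comparator.drug_daily, low: 2.1, high: 3.5}
- {path: initial_distribution.Severe, low: 0.0445, high: 1.0}
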