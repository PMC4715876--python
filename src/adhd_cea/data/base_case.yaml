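# Base-case model inputs: guanfacine-XR adjunctive to a long-acting stimulant
# versus long-acting stimulant monotherapy, pediatric ADHD, Canada (2013 $CA).
# Weekly cycles over a 1-year horizon; stage 1 = weeks 0-8 (all on treatment),
# week-8 non-responders (Moderate/Severe) discontinue and are absorbed.

settings:
  horizon_weeks: 52
  stage1_weeks: 8
  response_states: [Normal, Mild]
  structural_variant: base
  wtp_threshold: 50000
  renormalize_rows: true

initial_distribution:
  Normal: 0.0000
  Mild: 0.0352
  Moderate: 0.9055
  Severe: 0.0593

utilities:
  Normal: 0.839
  Mild: 0.787
  Moderate: 0.578
  Severe: 0.444

costs:
  weekly_medical:
    Normal: 4.71
    Mild: 4.76
    Moderate: 13.63
    Severe: 28.38
  weekly_productivity:
    Normal: 14.60
    Mild: 15.38
    Moderate: 60.30
    Severe: 125.10

arms:
  intervention:
    name: "GXR + long-acting stimulant"
    # GXR $3.89/day plus market-share-weighted long-acting stimulant $2.80/day
    drug_daily: 6.69
    transitions:
      p:
        - [0.766, 0.231, 0.003, 0.000]
        - [0.112, 0.817, 0.070, 0.000]
        - [0.003, 0.258, 0.737, 0.003]
        - [0.000, 0.000, 0.361, 0.550]   # raw row sum 0.911; renormalized on load
      se:
        - [0.041, 0.041, 0.001, 0.000]
        - [0.014, 0.016, 0.011, 0.000]
        - [0.001, 0.019, 0.019, 0.001]
        - [0.000, 0.000, 0.102, 0.102]
  comparator:
    name: "Long-acting stimulant monotherapy"
    drug_daily: 2.80
    transitions:
      p:
        - [0.759, 0.238, 0.003, 0.000]
        - [0.081, 0.826, 0.093, 0.000]
        - [0.002, 0.192, 0.801, 0.004]
        - [0.000, 0.000, 0.236, 0.763]
      se:
        - [0.056, 0.055, 0.001, 0.000]
        - [0.013, 0.017, 0.014, 0.000]
        - [0.001, 0.015, 0.015, 0.003]
        - [0.000, 0.000, 0.068, 0.068]

# Adverse-event incidences/disutilities are not part of the published input
# tables (they live in an earlier US analysis); the list defaults to empty
# and accepts entries of the form:
#   - name: somnolence
#     incidence: {intervention: 0.10, comparator: 0.02}
#     disutility: 0.05
#     duration_weeks: 4
aes: []

uncertainty:
  n_sims: 10000
  utility_se_frac: 0.10
  cost_low_frac: 0.75
  cost_high_frac: 1.25
  ae_duration_low_frac: 0.5
  ae_duration_high_frac: 1.5

# Long-acting stimulant market (daily cost $CA/day, Canadian market share);
# the weighted average reproduces the comparator drug_daily of $2.80.
drug_market:
  MAS-XR:
    daily_cost: 3.24
    share: 0.142
  MPH-CR:
    daily_cost: 1.77
    share: 0.153
  OROS-MPH:
    daily_cost: 2.76
    share: 0.461
  OROS-MPH-generic:
    daily_cost: 1.91
    share: 0.064
  LDX:
    daily_cost: 3.75
    share: 0.180

# Inputs for the severity allocation of annual medical costs.
cost_allocation:
  nonadhd_median_annual: 245.0
  adhd_median_annual: 322.0
  adhd_mean_annual: 738.0
  severe_multiplier: 2.0
  mild_percentile: 3.52
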