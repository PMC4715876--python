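# Methods note

This note documents the modeling choices, parameter conventions, numerical
methods, and open design decisions in `adhd_cea`. It describes what the
package computes; every number quoted here is reproducible from the packaged
base-case configuration.

## 1. Model structure

### Health states

CGI-S scores are collapsed to four ordinal states: Normal (CGI-S 1),
Mild (2–3), Moderate (4–5), Severe (6–7), indexed 0–3. "Response" is defined
by a configurable state set, default `{Normal, Mild}` (CGI-S ≤ 3). This is an
open design decision: an alternative response definition (e.g. Normal only)
changes response-based metrics and the two-stage absorption rule; it is
exposed as `settings.response_states`.

### Cohort engine

A cohort distribution over the four states is propagated in weekly cycles,
`occ(t) = occ(t−1) · P_arm`, for a 52-week horizon starting from the shared
baseline distribution (0, 0.0352, 0.9055, 0.0593). The model is two-stage:

- **Stage 1 (weeks 1–8):** everyone transitions under the arm's matrix while
  on treatment.
- **Stage 2 (weeks 9–52), base variant:** at the end of each week ≥ 8, mass in
  non-response states (Moderate, Severe) is moved to a permanent off-treatment
  compartment that preserves the severity state (no further transitions, no
  drug cost). Responders keep transitioning on treatment; if they later
  relapse into a non-response state they are absorbed at that point.

Structural variants:

- `maintain_on_treatment`: no absorption; everyone transitions and is charged
  drug cost for all 52 weeks.
- `stabilize_after_stage1`: week-8 non-responders are absorbed as in the base
  variant, then the entire occupancy is frozen for weeks 9–52; week-8
  responders remain on treatment (and are charged drug cost) but no longer
  transition.

A structural consequence worth stating explicitly: in patient-weeks spent in
response states, both alternatives weakly dominate the base rule
(`maintain ≥ base` and `stabilize ≥ base`). Under `stabilize`, week-8
responders can never relapse, while under the base rule responders keep
transitioning and are absorbed on relapse, so `stabilize` does **not**
generally produce fewer response weeks than the base rule. On the packaged
comparator arm the ordering is maintain (35.70) > stabilize (32.13) >
base (12.40).

The cohort engine is validated against an independent individual-level
microsimulation (`adhd_cea.engine.microsimulate`, 200,000 sampled paths) under
all three variants; occupancy agrees within 3 binomial standard errors at
every week.

### Treatment exposure

`treatment_weeks = Σ_{t=1..52} on-treatment occupancy at t−1`, i.e. the week
in which a patient is found to be a non-responder is still a treated (and
drug-charged) week. The toggle `settings.drug_charge_final_week=False` stops
charging one week earlier. This is an open convention; the default charges
through the absorption week.

## 2. Outcomes

- **QALYs:** `(1/52) Σ_{t=1..52} occ(t)·u` minus adverse-event disutility
  `Σ_AE incidence × disutility × duration_weeks / 52`. Week-0 occupancy is not
  health experienced over a cycle and is excluded.
- **Costs:** drug = `treatment_weeks × 7 × daily price`; medical and
  productivity = `Σ_t occ(t) · weekly state cost` (all occupancy, on or off
  treatment, accrues medical and productivity cost). MoH perspective =
  drug + medical; societal = MoH + productivity. No discounting (1-year
  horizon).
- **Comparison:** incremental QALYs and per-perspective incremental costs and
  ICERs. Dominance is handled per perspective: if the intervention gains QALYs
  and saves money it is flagged `intervention_dominant` (ICER reported as
  undefined/NaN rather than a negative number), and symmetrically for
  `comparator_dominant`.
- **Response metrics:** week-8 response rates, incremental response rate,
  NNT = 1 / incremental response rate, and patient-weeks in response states
  over weeks 1–52.

Base-case results from the packaged inputs: QALYs 0.6593 (adjunctive) vs
0.6288 (monotherapy), ΔQALY 0.0305; ΔC $662.81 (MoH) and $331.89 (societal);
ICERs $21,744 and $10,887 per QALY; Δresponse 13.6 points, NNT 7.33.

## 3. Parameters and units

All parameters live in one YAML configuration (see
`src/adhd_cea/data/base_case.yaml`). Units: utilities are per-year weights;
state costs are weekly Canadian dollars; drug prices are daily Canadian
dollars; transition matrices are weekly probabilities with per-cell standard
errors; adverse events have per-course incidence, utility decrement, and
duration in weeks (base case: none). Defaults: horizon 52 weeks, stage 1 = 8
weeks, willingness-to-pay threshold $50,000/QALY.

Transition-matrix rows that do not sum to 1 are renormalized at load with a
`ConfigWarning` (the packaged adjunctive-arm Severe row sums to 0.911 as
published); the raw values are retained on the `TransitionMatrix` object and
renormalization can be disabled via `settings.renormalize_rows`.

### Severity-based cost allocation (`adhd_cea.costing`)

Annual medical costs per state are derived from an overall annual mean cost
(C̄ = $738), the cost at the 0th percentile of a reference cost distribution
($245), the cost at the 50th percentile ($322), a Severe multiplier (2), and a
Normal/Mild percentile anchor (3.52):

- Normal = $245 (0th percentile).
- Mild = mean of the 0th-percentile cost and the linear interpolation at the
  anchor percentile: ($245 + $250.42)/2 = $247.71.
- Severe = 2 × C̄ = $1,476.
- Moderate is back-solved so the initial-distribution-weighted mean equals C̄:
  $708.73.

Weekly costs are annual/52 ($4.71, $4.76, $13.63, $28.38). The comparator
daily drug price is a market-share-weighted mean over five long-acting
stimulant products ($2.80/day).

## 4. Transition estimation (`adhd_cea.estimation`)

From a patient-level weekly CGI-S panel (`patient_id, arm, week, cgis`):

- **LOCF imputation:** missing post-baseline visits are filled from the last
  observed *post-baseline* value; the baseline observation is never carried
  forward. Patients with no post-baseline observations contribute no
  transitions.
- **Empirical matrix:** transition counting with binomial standard errors;
  rows with no observations are flagged with a warning and left as NaN.
- **Proportional-odds ordered logit:** destination state given origin state,
  `P(Y ≤ k | origin j) = logistic(θ_k − β_j)` (Normal origin as reference).
  Fitted by maximum likelihood with `scipy.optimize` (BFGS, gradient tolerance
  1e-8) on a transformed parameterization that enforces θ ordering
  (θ₁ plus log-increments). If the fit does not converge or any parameter
  exceeds 15 in absolute value (quasi-separation), the model is refitted with
  a ridge penalty of 1e-4 and a warning. The covariance is the inverse
  numerical Hessian in the natural (β, θ) space; cell-probability standard
  errors come from the delta method. The estimator is cross-checked in the
  test suite against `statsmodels` `OrderedModel` and against parameter
  recovery on synthetic panels.

## 5. Synthetic panels (`adhd_cea.synthetic`)

`simulate_panel` draws individual weekly state paths from a given transition
matrix and initial distribution, maps states to CGI-S scores uniformly within
each band, and applies missingness — either missing-completely-at-random at a
given rate or monotone dropout. Baseline is always observed. Scope: the
generator exists to validate the estimators (LOCF, empirical counting, ordered
logit) with known ground truth; it is not a clinical trial simulator (no
covariates, no visit windows, no informative missingness).

## 6. Uncertainty analysis (`adhd_cea.uncertainty`)

- **One-way (tornado):** each dot-addressed scalar is set to its low and high
  bound with everything else at base; the table reports per-bound ICERs,
  dominance flags, and is sorted by ICER spread (dominance counts as infinite
  spread). A default range file (`src/adhd_cea/data/owsa_ranges.yaml`, ±25%
  within natural bounds) ships with the package.
- **PSA:** per draw, every transition cell is sampled from a beta distribution
  parameterized by method of moments from its mean and standard error
  (ν = m(1−m)/s² − 1), then rows are renormalized; cells with s = 0 or
  m ∈ {0, 1} are point masses, and rows containing only point masses are left
  bit-identical to base. Standard errors implying ν ≤ 0 are clipped to
  0.99·√(m(1−m)) with a warning. Utilities are beta-sampled with a default
  standard error of 10% of the mean (the configuration prints no utility
  standard errors, so this is an explicit assumption, configurable via
  `uncertainty.utility_se_frac`). Costs (state costs and drug prices) are
  triangular with mode at base and bounds at ±25%. Adverse-event durations are
  uniform on [0.5·base, 1.5·base]. Each draw gets an independent substream
  spawned from the master seed keyed by draw index, so any draw is
  reproducible in isolation. A Dirichlet row sampler is available as an
  alternative (`uncertainty.dirichlet_rows`).
- **CEAC:** probability that net monetary benefit λ·ΔQ − ΔC ≥ 0 across draws,
  per perspective, over a willingness-to-pay grid ($0–$100,000 in $5,000
  steps by default).

At 10,000 draws from the packaged inputs, the probability of
cost-effectiveness at $50,000/QALY is ≈ 0.89 (MoH) and ≈ 0.94 (societal).
A probability of ≥ 0.99 at this threshold is demanding under these inputs:
the sampled ΔQALY has a standard deviation of roughly 0.016 around a mean of
0.030, so draws where λ·ΔQ falls below ΔC are not rare. The sampling
machinery was validated against an independent brute-force resampler (means
agree within Monte Carlo error), and neither removing cost variance nor
common-random-number coupling across arms raises both perspectives above
0.99; reaching that level would require materially smaller input standard
errors or a different distributional assumption than those stated above.

## 7. Numerical and reproducibility choices

- Pure `numpy` linear algebra for cohort propagation; no discounting or
  half-cycle correction (weekly cycles over one year make the correction
  negligible relative to parameter uncertainty).
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  PSA uses `SeedSequence(entropy=seed, spawn_key=(draw,))`.
- Deterministic outputs are bit-reproducible across runs; sorting in the
  tornado table uses a stable mergesort so equal spreads order by parameter
  path.
- JSON outputs keep full float precision; CSV tables are for human reading.

## 8. Limitations

- One-year horizon; no extrapolation, mortality, or discounting.
- The state-preserving absorption rule assumes non-responders' severity is
  frozen after discontinuation, which ignores both deterioration and natural
  improvement off treatment.
- Utilities and their uncertainty are external inputs; the 10%-of-mean
  standard-error default is an assumption, not an estimate.
- PSA treats transition cells as independent betas renormalized per row,
  which slightly distorts the implied row-wise Dirichlet correlation
  structure (the alternative Dirichlet sampler is provided).
- The synthetic panel generator supports only MCAR and monotone-dropout
  missingness.
- Costs and prices are fixed to the packaged jurisdiction and year; no
  inflation adjustment is applied.
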