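# adhd-cea

A Markov cohort cost-utility model for guanfacine extended-release (GXR) given
as an adjunct to long-acting psychostimulants, versus psychostimulant
monotherapy, in children and adolescents with ADHD whose symptoms are
suboptimally controlled on a stimulant alone.

## The scientific problem

A sizeable fraction of pediatric ADHD patients respond only partially to
long-acting stimulants. One option is to add a non-stimulant — GXR — on top of
the stimulant. The clinical question (does symptom severity improve?) has been
studied in randomized trials; the economic question is whether the extra drug
cost buys enough extra health to be worthwhile to a public payer. This package
answers that question with a decision-analytic model: it converts
trial-measured severity dynamics into quality-adjusted life-years (QALYs) and
costs over one year, and reports incremental cost-effectiveness ratios (ICERs)
from a Ministry-of-Health (MoH) and a societal perspective.

## The model

Disease status is summarized by the Clinical Global Impression–Severity
(CGI-S) scale, collapsed to four ordinal health states:

| State    | CGI-S | Utility | Weekly medical cost | Weekly productivity loss |
|----------|-------|---------|--------------------:|-------------------------:|
| Normal   | 1     | 0.839   | $4.71               | $14.60                   |
| Mild     | 2–3   | 0.787   | $4.76               | $15.38                   |
| Moderate | 4–5   | 0.578   | $13.63              | $60.30                   |
| Severe   | 6–7   | 0.444   | $28.38              | $125.10                  |

A cohort starts from the trial's baseline severity distribution and moves
between states in weekly cycles according to an arm-specific 4×4 transition
matrix for 52 weeks. The model has two stages: an 8-week titration/response
stage, after which patients still Moderate or Severe are deemed non-responders,
stop study treatment, and remain in their severity state for the rest of the
year (a state-preserving absorbing rule). Responders (Normal/Mild) continue on
treatment and keep transitioning. Two structural variants relax this rule:
`maintain_on_treatment` (nobody stops; drug charged all 52 weeks) and
`stabilize_after_stage1` (week-8 occupancy frozen; responders still on drug).

Per-arm outputs: QALYs `(1/52)·Σ_t occupancy(t)·u`, drug cost (treatment-weeks
× 7 × daily price), medical and productivity costs from weekly state costs,
week-8 response rate, and patient-weeks spent in response states. Comparisons
report incremental QALYs/costs, per-perspective ICERs with dominance handling,
the incremental response rate, and number needed to treat (NNT).

Beyond the deterministic model the package includes:

- **Severity-based cost allocation** (`adhd_cea.costing`): derives the four
  annual state costs from an overall mean cost and percentile anchors, and the
  market-share-weighted daily stimulant price.
- **Transition estimation** (`adhd_cea.estimation`): last-observation-carried-
  forward imputation (post-baseline only), empirical transition counting, and
  a proportional-odds ordered-logit estimator of the transition matrix with
  delta-method standard errors.
- **Synthetic trial panels** (`adhd_cea.synthetic`): patient-level weekly
  CGI-S panel generator for validating the estimators.
- **Uncertainty analysis** (`adhd_cea.uncertainty`): one-way sensitivity
  (tornado table), structural variants, and probabilistic sensitivity analysis
  (PSA) with cost-effectiveness acceptability curves.

## Worked example

```python
import warnings
from adhd_cea import load_base_case, run_model
from adhd_cea.config import ConfigWarning

with warnings.catch_warnings():
    warnings.simplefilter("ignore", ConfigWarning)  # one published row sums to 0.911
    config = load_base_case()

run = run_model(config)
c = run.comparison
print(f"QALYs:      adjunctive {run.intervention.qalys:.4f} | "
      f"monotherapy {run.comparator.qalys:.4f} | incremental {c.incremental_qaly:.4f}")
print(f"Cost (MoH): adjunctive ${run.intervention.total_cost['moh']:.2f} | "
      f"monotherapy ${run.comparator.total_cost['moh']:.2f} | "
      f"incremental ${c.incremental_cost['moh']:.2f}")
print(f"ICER:       ${c.icer['moh']:,.0f}/QALY (Ministry of Health) | "
      f"${c.icer['societal']:,.0f}/QALY (societal)")
print(f"Week-8 response: +{100*c.incremental_response_rate:.1f} percentage points "
      f"| NNT {c.nnt_week8:.2f}")
```

Output:

```
QALYs:      adjunctive 0.6593 | monotherapy 0.6288 | incremental 0.0305
Cost (MoH): adjunctive $1609.86 | monotherapy $947.05 | incremental $662.81
ICER:       $21,744/QALY (Ministry of Health) | $10,887/QALY (societal)
Week-8 response: +13.6 percentage points | NNT 7.33
```

The same run is available from the command line:

```bash
adhd-cea run --out results/base_case.json
# incremental QALY: 0.0305
# incremental cost (MoH): $663; ICER: $21,744/QALY
# incremental cost (societal): $332; ICER: $10,887/QALY
```

Other subcommands: `adhd-cea owsa`, `adhd-cea psa`, `adhd-cea derive-costs`,
`adhd-cea simulate-panel`, `adhd-cea estimate-transitions` (see `--help`).

## Reproduction

`scripts/acceptance.py` recomputes the headline results from the packaged
base-case inputs — base-case incremental QALYs, absolute QALYs in the
adjunctive arm, both ICERs, incremental MoH cost, NNT and incremental week-8
response rate, the maintain-on-treatment ICER, and the PSA probability of
cost-effectiveness at $50,000/QALY over 10,000 draws:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes a JSON map of `{"<target id>": {"value": ..., "n": ...}}` where `n`
is the number of weekly cycles (deterministic targets) or PSA draws. The seed
affects only the PSA target; deterministic targets are bit-reproducible.

## Configuration

All inputs live in a single YAML file
(`src/adhd_cea/data/base_case.yaml` is the packaged base case): initial
severity distribution, utilities, weekly state costs, per-arm daily drug cost
and transition matrix with standard errors, adverse events, model settings
(horizon, stage-1 length, response-state set, structural variant, willingness-
to-pay threshold), and PSA settings. `load_config(path)` loads and validates;
rows that do not sum to 1 are renormalized with a warning (raw values are
retained on the object).

See `docs/methods.md` for full methods, assumptions, and limitations.
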