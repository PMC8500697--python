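# File formats

All tables are UTF-8 CSV with a header row; dates are ISO-8601 (YYYY-MM-DD).

## indicators.csv
One row per location × day, days contiguous within location.

| column | meaning |
|---|---|
| location_id | location identifier (e.g. `L03`) |
| date | calendar day |
| mobility_decrease | proportional reduction from pre-pandemic mobility, [0, 1] |
| infection_rate | daily new SARS-CoV-2 infections per capita, [0, 1] |
| excess_mortality_rate | daily excess deaths per capita, [0, 1] |
| pandemic | boolean; all three indicators are 0 where false |

## studies.csv
One row per pre/mid-pandemic survey comparison.

`sample_id, location_id, disorder (MDD|anxiety), prev_pre, prev_mid, n_pre,
n_mid, mean_age, prop_female, design (longitudinal_random |
cross_sectional_random | longitudinal_quota | cross_sectional_quota),
combined_symptoms (bool), mid_start, mid_end`

## baseline_prevalence.csv
One row per disorder × location × age group × sex with draw columns
`draw_0 … draw_{n-1}` holding baseline prevalence proportions in (0, 1).

Key columns: `disorder, location_id, age_lo, age_hi, sex (female|male)`.

## populations.csv
`location_id, age_lo, age_hi, sex, population`

## severity_inputs.csv
`disorder, severity (asymptomatic|mild|moderate|severe), proportion, weight`
— proportions sum to 1 per disorder; the asymptomatic weight is 0.

## truth.json
Generator sidecar: the full synthetic config plus, per study, the true
pre/mid prevalence, the systematic shift, the sample random effects and the
window-averaged transformed exposures.

## Fitted-model files
- `coefficients_<disorder>.csv`: one row per covariate and model
  (indicator/final) with mean, ranked 95% UI bounds and p-value.
- `draws_<disorder>.csv`: one row per covariate with `draw_*` columns, the
  fitted random-effect variances, and the index p-threshold the fit used.

## Output tables
- `adjusted_prevalence.csv`: per cell, `baseline_draw_*`, `final_draw_*`,
  `additional_draw_*` (annual point prevalence draws).
- `change_table.csv`: aggregated baseline/additional/final rates per 100 000,
  percent change (mean-of-ratios and ratio-of-means), counts; ranked-draw UIs.
- `burden_table.csv`: per cell YLD and DALY rates per 100 000 and counts
  (final, ratio-rescaled baseline, additional) with ranked-draw UIs.
- `loco_report.csv`: per held-out observation, observed vs predicted shift
  with UI and coverage flag.
- `manifest.json`: seed, package version, SHA-256 hashes of inputs/outputs.
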