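# mhshock

Estimating how a population shock — the COVID-19 pandemic year 2020 — changed
the prevalence and burden of major depressive disorder (MDD) and anxiety
disorders. The package is written for epidemiologists and burden-of-disease
modellers who want a transparent, fully testable implementation of the
estimation chain on synthetic data with known ground truth.

## The model

Each survey comparison contributes the change in logit prevalence
`y_i = logit(p_mid) − logit(p_pre)` with a delta-method binomial variance.
The chain has two meta-regression steps, both normal–normal hierarchical
models with a random intercept per survey sample (REML variance components,
verified against R `metafor`):

1. **Indicator model** — `y` on three daily pandemic-impact indicators
   simultaneously (decrease in human mobility; √ daily SARS-CoV-2 infection
   rate; √ daily excess mortality rate), no global intercept, random slopes
   on the indicators, a directional (nonnegativity) prior on excess mortality
   because of its r ≈ 0.8 collinearity with the other two, and the additive
   quota-sample bias controlled. The significant coefficients define a scalar
   **COVID-19 impact index** per location-day:
   `index = Σ_j b_j · x_j  (p_j < 0.05)`.
2. **Final model** — `y = (b_index + b_age·age + b_sex·pf + …)·index +
   b_csq·quota + RE`, with age, sex and design flags as effect modifiers
   (prediction is exactly zero at zero impact) and the cross-sectional
   quota-sample flag as the single additive bias; candidates are removed by
   AIC backward elimination.

Uncertainty propagates as 1000 seeded coefficient draws; every 95%
uncertainty interval is the 25th/975th ranked draw. Baseline prevalence
draws are shifted on the logit scale per draw and per day, averaged over the
year into point prevalence, split into severity states, and multiplied by
disability weights to give YLDs; DALYs equal YLDs for these disorders.
Baseline burden is recovered by the per-draw baseline/final prevalence ratio.
Validation is leave-one-country-out cross-validation plus a
parameter-recovery harness over seeded replicate simulations.

## Worked example

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_fit_meta_regression.py --seed 1
python analysis/03_adjust_prevalence.py --seed 1
python analysis/04_burden.py --seed 1
python analysis/05_validate.py --seed 1
```

Step two of the fit prints, for anxiety disorders (seed 1):

```
        covariate          role    mean  lower    upper      p     model
mobility_decrease     indicator  0.8584 0.2819   1.4019 0.0031 indicator
   sqrt_infection     indicator 14.4143 4.7437  24.3221 0.0033 indicator
      sqrt_excess     indicator 33.8922 0.0000 153.8759 0.4614 indicator
         cs_quota additive_bias  0.6289 0.5369   0.7168 0.0000 indicator
            index         index  0.9405 0.8158   1.0682 0.0000     final
combined_symptoms      modifier  0.2373 0.0323   0.4363 0.0149     final
         cs_quota additive_bias  0.6412 0.5510   0.7294 0.0000     final
```

Read: mobility decrease and infection rate are significantly associated with
the rise in logit prevalence (0.86 and 14.4 against generative truths 0.9 and
13.8); excess mortality is not (it is collinear with the other two and its
huge UI reflects the tiny scale of √excess), so it is excluded from the
index. In the final model the quota-sample flag adds 0.64 to the logit change
even at zero impact — the design bias the generator planted at 0.6 — and the
combined-symptom instrument inflates the anxiety change (truth 0.3). The
adjustment stage then reports, per disorder, the population-weighted
baseline/additional/final prevalence per 100 000 and percent change with
ranked-draw UIs, e.g. (seed 1)
`anxiety: prevalence rises from 3913 to 5739 per 100k (46.7% [20.9 to 78.3])`
— the synthetic world is hit harder than any real 2020 estimate, because its
indicator levels persist all year.

The same stages are available as a CLI (`mhshock simulate|fit|adjust|burden|
validate|run-all --seed N --draws 1000 --out-dir …`) writing the tables
documented in `docs/formats.md`.

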