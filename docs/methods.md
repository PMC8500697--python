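# Methods

`mhshock` re-implements, as a tested pipeline over synthetic data, an
estimation chain for the change in prevalence and burden of major depressive
disorder (MDD) and anxiety disorders attributable to a population shock — the
COVID-19 pandemic year 2020 — from survey comparisons, daily impact
indicators, baseline prevalence surfaces, and severity/disability inputs.

## Outcome and sampling model

Each survey comparison contributes one observation

    y_i = logit(p_mid,i) − logit(p_pre,i),
    se_i² = 1/(n_pre p_pre q_pre) + 1/(n_mid p_mid q_mid)

(the delta-method binomial variance). Prevalences of exactly 0 or 1 are
rejected unless the continuity correction is enabled (add 0.5 cases and 1
observation to the offending wave); the default is to reject, because a
boundary prevalence in a population survey of these sizes signals a data
problem rather than a zero-prevalence population.

## Step one: indicator model and impact index

The three pandemic-impact indicators are the proportional decrease in human
mobility (untransformed), and the daily SARS-CoV-2 infection and excess
mortality rates (square-root transformed to correct positive skew). The model
is a normal–normal hierarchical meta-regression with **no global intercept**
(change must vanish at zero impact):

    y_i ~ N(x_i'β + u_{s(i)} + z_i'v_{s(i)},  se_i²),
    u_s ~ N(0, τ₀²),  v_s ~ N(0, τ₁² I)

with a random intercept per unique sample s and random slopes (shared
variance τ₁²) on the three indicators, grouped by the same sample id. The
excess-mortality coefficient is fitted under a **directional prior**
implemented as a nonnegativity constraint (active-set GLS: the coefficient is
pinned at the 0 boundary when the unconstrained solution violates the sign,
and every posterior draw is clipped to the constraint). The additive bias
flag for cross-sectional market-research/quota samples is controlled for in
this model too; leaving it out would fold a large design offset into the
random-intercept variance and destroy the indicators' precision. Bias
covariates never enter the index.

The **impact index** for an exposure x is the linear combination of the
indicator coefficients that are significant at p < 0.05 with the transformed
exposures; insignificant indicators (typically excess mortality, which is
collinear with the other two at r ≈ 0.8) are excluded. Zero exposure gives
exactly zero index. When the pipeline or a cross-validation fold finds *no*
significant indicator, the index is built from all indicator coefficients and
the fallback is logged/flagged, so the chain stays defined on low-power
subsets.

## Step two: final model with effect modifiers

    y_i ~ N( (b_index + b_age·age_i + b_sex·pf_i + b_comb·c_i + …)·index_i
             + b_csq·quota_i + u_{s(i)} + w_{s(i)}·index_i,  se_i² )

Age, sex (proportion female), the combined-symptom-instrument flag and the
remaining design flags act as *effect modifiers* multiplying the index, so
predicted change remains zero at zero impact; the cross-sectional quota flag
is the single additive term (its pre-pandemic baseline came from a different,
random, sample). Covariates are used uncentred (per-year age, raw proportion
female). Candidates are removed by backward elimination: the least
significant candidate (ties broken by the smaller absolute standardised
coefficient) is dropped while the AIC improves; the index is always retained.
Bias covariates are set to their reference (0) for population prediction.

## Estimation, draws and p-values

The marginal likelihood is evaluated by per-group Cholesky factorisation of
V_g = diag(se²) + Z_g D Z_g'; fixed effects are profiled out by (sign-
constrained) GLS and the two random-effect SDs are optimised by Nelder–Mead.
**REML** is the default for the variance components — the standard
meta-analytic choice; plain ML is available (`method="ml"`) and both modes
are verified against R `metafor` to ~5 decimals in the test suite. Reported
log-likelihood and AIC are ordinary-ML values at the optimum so that AICs
remain comparable across fixed-effect specifications during elimination.

Uncertainty is propagated as 1000 seeded draws of the fixed effects from the
asymptotic multivariate normal N(β̂, (X'V̂⁻¹X)⁻¹), clipped to any sign
constraints. p-values are two-sided normal approximations from the draw
mean/SD; p < 0.05 is the significance rule throughout. All 95% uncertainty
intervals are ranked-draw intervals: the 25th and 975th ranked of 1000 draws
(proportional ranks for other draw counts).

## Prevalence adjustment and accounting

For each disorder × location × age × sex baseline cell (1000 draws, from a
surface emulating a disease-model output for the no-pandemic counterfactual),
every day's shift is predicted from the cell's age midpoint and sex
(prop_female ∈ {0,1}, bias flags at reference) and the location's daily
index; draw d of the coefficients pairs with draw d of the baseline (common
random numbers). Daily adjusted prevalence is invlogit(logit(p_d) +
shift_d(t)); days before the location's pandemic start carry zero shift and
reproduce the baseline exactly (a dedicated fast path avoids logit/invlogit
round-trip error). The annual point prevalence is the equal-weight per-draw
mean over all days of the year, including pre-pandemic days.

Change accounting emits baseline/additional/final rates per 100 000, case
counts and percent change; final = baseline + additional holds per draw by
construction. Aggregation is population-weighted per draw, then summarised.
Two percent-change columns are emitted: the mean of per-draw ratios and the
ratio of aggregated means (`pct_change_of_means`); the latter is the column
that matches arithmetic done on published summary rows, and the two differ in
the third digit on dispersed draws.

## Burden

Prevalence is split multiplicatively into asymptomatic/mild/moderate/severe
states (proportions sum to 1 within 1e-9; conservation of the split holds to
1e-12) and converted to YLDs as Σ prevalence × disability weight, with an
optional scalar comorbidity multiplier (default 1.0) standing in for the
full-cause-list comorbidity microsimulation, which is out of scope. DALYs
equal YLDs exactly for these disorders (no years of life lost). Baseline
(no-pandemic) burden is the adjusted burden rescaled per draw by
baseline/final prevalence. The shipped severity proportions and disability
weights are **synthetic defaults for exercising the accounting**, not a GBD
extraction.

## Synthetic data generator

The generator defines the study conditions and records its ground truth:

- **Indicators.** Per location, a 3-dimensional latent Gaussian random walk
  with increment correlation matrix C (defaults r = 0.5 mobility–infection,
  0.8 mobility–excess, 0.8 infection–excess; PSD-checked, the offending pair
  named on failure) is standardised day-by-day and mapped linearly — with
  rare clipping — to realistic ranges: mobility decrease mean 0.35 (SD 0.15),
  daily infections mean 4e-4 per capita (SD 3e-4; ~9% of location-days clip
  to zero, matching pre-wave periods), daily excess deaths mean 4e-6 per
  capita. Linear maps keep the pooled Pearson correlations within ±0.1 of the
  request; the pandemic start is drawn per location in Feb–Apr 2020 and all
  indicators are exactly zero before it.
- **Surveys.** 50 comparisons per disorder by default: location uniform;
  design from {longitudinal/cross-sectional} × {random/quota} with quota
  cross-sections most common (0.35), mirroring the scarcity of random
  sampling mid-pandemic; mean age U(25, 60); proportion female U(0.4, 0.6);
  n per wave U(500, 5000); windows of 14–60 days inside the pandemic period.
  The true mid prevalence is invlogit(logit(p_pre) + shift) with the shift
  computed by the final-model formula at the configured truths plus a sample
  random intercept (SD 0.05) and per-indicator random slopes (SD 0.2); both
  waves are observed as independent binomials (the within-cohort covariance
  of longitudinal waves is not identified by the source material). The exact
  systematic shift, random effects and window-averaged exposures are stored
  in a sidecar and round-trip to 1e-12.
- **Baseline surfaces.** Seven age groups (15–85) × sex × location, female >
  male, age-peaked, 1–8% prevalence, 1000 logit-normal draws per cell, with
  plausible populations.

**Default coefficient truths and self-consistency.** The defaults place the
indicator coefficients at the published point values (mobility 0.9 for both
disorders; √infection 18.1 MDD / 13.8 anxiety; excess 0), the age modifiers
at −0.007 / −0.003 per year, the sex modifier at 0.1, the combined-symptom
modifier at 0.3 (anxiety), and the additive quota bias at 0.9 / 0.6. The
index coefficient truth is set to 1.25 (MDD) / 1.02 (anxiety) rather than a
published value: in a two-step procedure the index is calibrated on the same
data step two refits, so the modifier multiplier must average ≈1 over the
study covariate distribution — otherwise the step-one coefficients would
absorb the difference and no single set of truths could generate both fitted
tables. Only products of the index scale and the indicator coefficients are
identified.

**What passing tests do and do not show.** The generator emulates binomial
survey noise, design biases, between-sample heterogeneity and collinear
exposures, but not instrument-specific measurement error, non-binomial
clustering within surveys, seasonality in the indicators, or reporting delays
— so recovery results certify the estimation chain's internal consistency,
not its behaviour on any real dataset.

## Validation harness

- **Leave-one-country-out.** Both steps are refitted with each country's
  studies excluded; the held-out observed shifts are compared with predictive
  95% ranked-draw intervals combining fixed-effect draw spread, the fitted
  random-effect variances (intercept + index slope), and the observation's
  own sampling error. Folds where a covariate becomes degenerate, or where no
  indicator stays significant, are flagged, not dropped.
- **Recovery.** Seeded replicate simulations at a configured truth report
  per-coefficient bias, RMSE and interval coverage. Step-one recovery uses a
  scenario with modifier/bias truths at neutral values (the indicator model's
  own family) and the unconstrained excess coefficient: at a boundary truth
  the directional prior is deliberately conservative and shrinks its
  collinear companions, so chain consistency is assessed without it while the
  constraint has its own property tests. Step-two recovery fits the full
  candidate set (no elimination) so selection does not confound bias
  measurement; replicates in which no indicator reaches significance are
  skipped and counted. Coefficients that *multiply* the estimated index carry
  a small Jensen-type upward bias (the index's replicate-specific scale error
  enters as 1/c); this is negligible in absolute terms for the age modifier
  but material relative to small modifier truths at these study counts, which
  is why the acceptance summary reports the age and additive-bias recoveries
  rather than every modifier.

## Numerical choices and limitations

- Random-effect SDs are bounded in [0, 50] for the Nelder–Mead search;
  starting value 0.1.
- Elimination ties on p-value break by the smaller |standardised
  coefficient| for deterministic, order-independent behaviour.
- The step-two fit uses the posterior-mean (point) index per observation;
  per-draw indices are used for propagation and prediction. Fitting 1000
  draw-specific second-step models would not produce a single coefficient
  table and is not attempted.
- Window exposures average the *transformed* daily indicators over the study
  window; transform-then-average is the neutral choice where the aggregation
  order is unspecified.
- The optional trimming flag (default off) drops the configured worst
  fraction of observations by standardised marginal residual after an initial
  fit, then refits once.
- Problem sizes used by the shipped analyses and the acceptance summary —
  10 locations, 50 studies per disorder, 1000 draws, 20–40 replicates — were
  chosen to match the scale of the emulated study while keeping each fit in
  fractions of a second.
- Real-data features deliberately out of scope: the systematic review, the
  estimation of the indicator series themselves, disease-model internals and
  geographic cascades, and the comorbidity microsimulation.
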