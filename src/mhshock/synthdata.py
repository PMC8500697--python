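"""Seeded generative model for every input of the pipeline.

No machine-readable deposit accompanies the estimates this pipeline
re-implements, so all three inputs are emulated: (1) daily pandemic-impact
indicator series per location, (2) pre/mid-pandemic survey comparisons whose
mid-pandemic logit prevalence is the pre-pandemic value plus the model-implied
shift (so the estimation chain can be tested for parameter recovery against a
known truth), and (3) baseline prevalence surfaces with populations and
severity/disability inputs.

Indicator curves are correlated latent Gaussian random walks, standardised
day-by-day and mapped linearly (with rare clipping) into valid ranges, which
keeps the pairwise Pearson correlations under direct control; the defaults
reproduce the collinearity structure of the real indicators (r=0.5 between
mobility decrease and infection rate, r=0.8 between excess mortality and each
of the other two). All indicators are exactly zero before a per-location
pandemic start date drawn in Feb-Apr 2020.

Survey observation noise is binomial at the reported sample size,
independently in the two waves (the within-cohort covariance of longitudinal
waves is not identified by the source material, so waves are treated as
independent). Ground truth for every study — the systematic shift, the
random-effect contributions and the window-averaged exposures — is stored in a
sidecar table so that recovery is checkable to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .burden import SEVERITIES, SeverityInputs

__all__ = ["SyntheticConfig", "generate_indicators", "generate_baseline",
           "generate_surveys", "default_severity_inputs"]

YEAR_START = pd.Timestamp("2020-01-01")

AGE_GROUPS = ((15, 25), (25, 35), (35, 45), (45, 55), (55, 65), (65, 75), (75, 85))
AGE_WEIGHTS = np.array([0.18, 0.17, 0.16, 0.15, 0.13, 0.12, 0.09])
DESIGNS = ("longitudinal_random", "cross_sectional_random",
           "longitudinal_quota", "cross_sectional_quota")
DESIGN_PROBS = (0.25, 0.25, 0.15, 0.35)

#: generative truths: the published point coefficients of the estimation
#: chain this generator runs forward (indicator coefficients on the
#: transformed scale; modifiers multiply the impact index; the quota-sample
#: flag is the one additive bias term). ``b_index`` is set so that the
#: modifier multiplier (b_index + b_age*age + b_sex*pf + ...) averages ~1
#: over the generator's study covariate distribution: in a two-step chain the
#: index is calibrated on the same data that step two refits, so any
#: systematic departure of the mean multiplier from 1 would be reabsorbed
#: into the step-one coefficients — a self-consistency requirement of the
#: procedure, not a tunable.
DEFAULT_TRUE_COEFFICIENTS = {
    "MDD": {
        "b_mobility": 0.9, "b_sqrt_infection": 18.1, "b_excess_mort": 0.0,
        "b_index": 1.25,
        "b_index_modifiers": {"age": -0.007, "sex": 0.1, "combined_symptoms": 0.0},
        "b_cs_quota": 0.9,
    },
    "anxiety": {
        "b_mobility": 0.9, "b_sqrt_infection": 13.8, "b_excess_mort": 0.0,
        "b_index": 1.02,
        "b_index_modifiers": {"age": -0.003, "sex": 0.1, "combined_symptoms": 0.3},
        "b_cs_quota": 0.6,
    },
}

DEFAULT_CORRELATIONS = {"mobility_infection": 0.5, "mobility_excess": 0.8,
                        "infection_excess": 0.8}


def default_severity_inputs() -> dict:
    """Synthetic severity splits and disability weights (plausible values for
    testing the accounting; NOT a GBD extraction)."""
    return {
        "MDD": SeverityInputs(
            disorder="MDD",
            proportions={"asymptomatic": 0.15, "mild": 0.35,
                         "moderate": 0.35, "severe": 0.15},
            weights={"asymptomatic": 0.0, "mild": 0.145,
                     "moderate": 0.396, "severe": 0.658}),
        "anxiety": SeverityInputs(
            disorder="anxiety",
            proportions={"asymptomatic": 0.10, "mild": 0.40,
                         "moderate": 0.35, "severe": 0.15},
            weights={"asymptomatic": 0.0, "mild": 0.03,
                     "moderate": 0.133, "severe": 0.523}),
    }


@dataclass
class SyntheticConfig:
    n_locations: int = 10
    n_studies: int = 50          # survey comparisons per disorder
    days: int = 366              # calendar year 2020
    disorders: tuple = ("MDD", "anxiety")
    true_coefficients: dict = field(
        default_factory=lambda: {d: dict(v, b_index_modifiers=dict(v["b_index_modifiers"]))
                                 for d, v in DEFAULT_TRUE_COEFFICIENTS.items()})
    indicator_correlations: dict = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    survey_n_range: tuple = (500, 5000)
    re_sd_intercept: float = 0.05
    re_sd_indicator: float = 0.2
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_locations < 1 or self.n_studies < 1 or self.days < 2:
            raise ValueError("n_locations, n_studies >= 1 and days >= 2 required")
        if self.survey_n_range[0] < 1:
            raise ValueError("survey sample sizes must be >= 1")
        if self.re_sd_intercept < 0 or self.re_sd_indicator < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        self.correlation_matrix()  # raises if not PSD

    def correlation_matrix(self) -> np.ndarray:
        c = self.indicator_correlations
        r_mi = c["mobility_infection"]
        r_me = c["mobility_excess"]
        r_ie = c["infection_excess"]
        C = np.array([[1.0, r_mi, r_me],
                      [r_mi, 1.0, r_ie],
                      [r_me, r_ie, 1.0]])
        eig = np.linalg.eigvalsh(C)
        if eig.min() < -1e-10:
            pairs = {"mobility_infection": abs(r_mi),
                     "mobility_excess": abs(r_me),
                     "infection_excess": abs(r_ie)}
            worst = max(pairs, key=pairs.get)
            raise ValueError(
                f"indicator correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eig.min():.4f}); the offending pair is "
                f"most likely {worst!r} = {self.indicator_correlations[worst]}")
        return C

    def locations(self):
        return [f"L{str(i).zfill(2)}" for i in range(self.n_locations)]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


def _pandemic_start_offsets(config: SyntheticConfig, rng) -> dict:
    """Per-location pandemic start as a day offset from Jan 1. Drawn in
    Feb-Apr for full-year configs; scaled into the first third for short
    test series."""
    if config.days >= 150:
        lo, hi = 31, 120
    else:
        lo, hi = max(config.days // 6, 1), max(config.days // 3, 2)
    return {loc: int(rng.integers(lo, hi + 1)) for loc in config.locations()}


# indicator mapping: (mean, scale per unit latent walk, clip lo, clip hi).
# Magnitudes match the 2020 pandemic year: mobility reductions of 10-60%,
# estimated (not reported) daily infections around 4e-4 per capita, daily
# excess deaths around 4e-6 per capita.
_IND_MAP = {
    "mobility_decrease": (0.35, 0.15, 0.0, 0.90),
    "infection_rate": (4e-4, 3e-4, 0.0, 3e-3),
    "excess_mortality_rate": (4e-6, 2e-6, 0.0, 5e-5),
}


def generate_indicators(config: SyntheticConfig) -> pd.DataFrame:
    """Daily correlated indicator series per location, zero pre-pandemic."""
    C = config.correlation_matrix()
    # eigen decomposition handles the PSD-but-singular case (|r| = 1)
    w, V = np.linalg.eigh(C)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = config.rng(stage=1)
    starts = _pandemic_start_offsets(config, rng)
    dates = YEAR_START + pd.to_timedelta(np.arange(config.days), unit="D")

    frames = []
    for loc in config.locations():
        s = starts[loc]
        T = config.days - s
        vals = {k: np.zeros(config.days) for k in _IND_MAP}
        if T > 0:
            eps = rng.standard_normal((T, 3)) @ L.T
            walk = np.cumsum(eps, axis=0)
            x = walk / np.sqrt(np.arange(1, T + 1))[:, None]
            for j, (k, (mu, sc, lo, hi)) in enumerate(_IND_MAP.items()):
                vals[k][s:] = np.clip(mu + sc * x[:, j], lo, hi)
        frames.append(pd.DataFrame({
            "location_id": loc, "date": dates,
            "mobility_decrease": vals["mobility_decrease"],
            "infection_rate": vals["infection_rate"],
            "excess_mortality_rate": vals["excess_mortality_rate"],
            "pandemic": np.arange(config.days) >= s,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_baseline(config: SyntheticConfig):
    """Baseline prevalence surfaces (with draws), populations and severity
    inputs. Female prevalence exceeds male; surfaces are age-shaped and sit in
    a realistic 1-8% band."""
    rng = config.rng(stage=2)
    base_rate = {"MDD": 0.035, "anxiety": 0.045}
    sex_mult = {"female": 1.25, "male": 0.80}
    age_mult = np.array([0.85, 1.00, 1.10, 1.05, 0.95, 0.85, 0.75])

    rows, pop_rows = [], []
    for loc in config.locations():
        loc_eff = float(np.exp(rng.normal(0.0, 0.15)))
        total_pop = float(rng.uniform(2e6, 8e7))
        for (a_lo, a_hi), am, aw in zip(AGE_GROUPS, age_mult, AGE_WEIGHTS):
            for sex in ("female", "male"):
                pop = total_pop * (aw / AGE_WEIGHTS.sum()) * 0.5
                pop_rows.append({"location_id": loc, "age_lo": a_lo,
                                 "age_hi": a_hi, "sex": sex, "population": pop})
                for dis in config.disorders:
                    m = np.clip(base_rate[dis] * sex_mult[sex] * am * loc_eff,
                                0.011, 0.08)
                    draws = special.expit(special.logit(m)
                                          + rng.normal(0.0, 0.07, config.n_draws))
                    row = {"disorder": dis, "location_id": loc,
                           "age_lo": a_lo, "age_hi": a_hi, "sex": sex}
                    row.update({f"draw_{i}": v for i, v in enumerate(draws)})
                    rows.append(row)
    surfaces = pd.DataFrame(rows)
    populations = pd.DataFrame(pop_rows)
    return surfaces, populations, default_severity_inputs()


def _true_index_parts(coef: dict, x_mob, x_sqi, x_sqe):
    return (coef["b_mobility"] * x_mob + coef["b_sqrt_infection"] * x_sqi
            + coef["b_excess_mort"] * x_sqe)


def true_shift(coef: dict, x_mob, x_sqi, x_sqe, mean_age, prop_female,
               combined, cs_quota_flag, re_intercept=0.0, re_mob=0.0,
               re_sqi=0.0, re_sqe=0.0):
    """Closed-form generative shift: (b_index + modifiers) * index +
    additive quota bias + sample-level random effects."""
    mods = coef["b_index_modifiers"]
    modifier_sum = (coef.get("b_index", 1.0) + mods["age"] * mean_age
                    + mods["sex"] * prop_female
                    + mods["combined_symptoms"] * combined)
    index = _true_index_parts(coef, x_mob, x_sqi, x_sqe)
    re_part = re_intercept + re_mob * x_mob + re_sqi * x_sqi + re_sqe * x_sqe
    return modifier_sum * index + coef["b_cs_quota"] * cs_quota_flag + re_part


def generate_surveys(config: SyntheticConfig, indicators: pd.DataFrame,
                     baseline: pd.DataFrame | None = None):
    """Survey comparisons generated forward from the final-model formula.

    Returns ``(studies, truth)``: the observed records (binomial noise at the
    stated n in both waves) and a sidecar with the systematic shift, random
    effects and window-averaged transformed exposures per study.
    """
    rng = config.rng(stage=3)
    ind = indicators.copy()
    ind["date"] = pd.to_datetime(ind["date"])
    by_loc = {loc: g.sort_values("date").reset_index(drop=True)
              for loc, g in ind.groupby("location_id")}

    base_mean = {}
    if baseline is not None:
        dcols = [c for c in baseline.columns if c.startswith("draw_")]
        for (dis, loc), g in baseline.groupby(["disorder", "location_id"]):
            base_mean[(dis, loc)] = float(g[dcols].to_numpy().mean())

    n_lo, n_hi = config.survey_n_range
    studies, truths = [], []
    k = 0
    for dis in config.disorders:
        coef = config.true_coefficients[dis]
        for _ in range(config.n_studies):
            loc = config.locations()[int(rng.integers(config.n_locations))]
            g = by_loc[loc]
            pandemic_idx = np.flatnonzero(g["pandemic"].to_numpy())
            if pandemic_idx.size == 0:
                raise ValueError(f"no pandemic indicator coverage for "
                                 f"location {loc!r}")
            start0 = pandemic_idx[0]
            max_len = min(60, len(g) - start0)
            length = int(rng.integers(min(14, max_len), max_len + 1))
            w_start = int(rng.integers(start0, len(g) - length + 1))
            win = g.iloc[w_start:w_start + length]
            x_mob = float(win["mobility_decrease"].mean())
            x_sqi = float(np.sqrt(win["infection_rate"]).mean())
            x_sqe = float(np.sqrt(win["excess_mortality_rate"]).mean())

            design = DESIGNS[int(rng.choice(len(DESIGNS), p=DESIGN_PROBS))]
            combined = float(rng.random() < 0.2)
            mean_age = float(rng.uniform(25.0, 60.0))
            prop_female = float(rng.uniform(0.4, 0.6))
            csq = float(design == "cross_sectional_quota")

            anchor = base_mean.get((dis, loc), 0.04)
            p_pre = float(np.clip(anchor * np.exp(rng.normal(0.0, 0.15)),
                                  0.01, 0.12))
            re_int = rng.normal(0.0, config.re_sd_intercept)
            re_mob, re_sqi_c, re_sqe_c = rng.normal(0.0, config.re_sd_indicator, 3)
            shift = true_shift(coef, x_mob, x_sqi, x_sqe, mean_age, prop_female,
                               combined, csq, re_int, re_mob, re_sqi_c, re_sqe_c)
            p_mid = float(special.expit(special.logit(p_pre) + shift))

            n_pre = int(rng.integers(n_lo, n_hi + 1))
            n_mid = int(rng.integers(n_lo, n_hi + 1))
            obs_pre = _binom_prev(rng, n_pre, p_pre)
            obs_mid = _binom_prev(rng, n_mid, p_mid)

            sid = f"S{str(k).zfill(4)}"
            k += 1
            studies.append({
                "sample_id": sid, "location_id": loc, "disorder": dis,
                "prev_pre": obs_pre, "prev_mid": obs_mid,
                "n_pre": n_pre, "n_mid": n_mid, "mean_age": mean_age,
                "prop_female": prop_female, "design": design,
                "combined_symptoms": bool(combined),
                "mid_start": str(win["date"].iloc[0].date()),
                "mid_end": str(win["date"].iloc[-1].date()),
            })
            truths.append({
                "sample_id": sid, "disorder": dis,
                "true_prev_pre": p_pre, "true_prev_mid": p_mid,
                "true_shift": shift,
                "true_index": _true_index_parts(coef, x_mob, x_sqi, x_sqe),
                "re_intercept": re_int, "re_mobility": re_mob,
                "re_sqrt_infection": re_sqi_c, "re_sqrt_excess": re_sqe_c,
                "x_mobility": x_mob, "x_sqrt_infection": x_sqi,
                "x_sqrt_excess": x_sqe,
            })
    return pd.DataFrame(studies), pd.DataFrame(truths)


def _binom_prev(rng, n, p):
    """Observed prevalence: binomial draw with a continuity fallback so the
    logit stays finite (boundary draws are vanishingly rare at these n)."""
    x = int(rng.binomial(n, p))
    if x == 0 or x == n:
        return (x + 0.5) / (n + 1.0)
    return x / n
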