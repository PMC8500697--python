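"""Two-step meta-regression on the change in logit disorder prevalence.

The outcome of every model here is ``delta_logit``: the difference between the
logit of mid-pandemic and pre-pandemic prevalence of a disorder in one survey
comparison, with a delta-method sampling variance from the two binomial waves.

Step one ("indicator model") regresses delta_logit simultaneously on the three
pandemic-impact indicators — proportional decrease in human mobility, the
square root of the daily SARS-CoV-2 infection rate, and the square root of the
daily excess mortality rate — with no global intercept (the change must vanish
when the pandemic impact is zero), a random intercept per unique survey sample
and random slopes on the indicators, and a directional (nonnegativity)
constraint on the excess-mortality coefficient, which is heavily collinear
with the other two indicators. The significant step-one coefficients are then
collapsed into a single scalar *impact index* per observation.

Step two ("final model") regresses delta_logit on the impact index with age,
sex and study-design covariates acting as *effect modifiers* (they multiply
the index, so predicted change is still zero at zero impact); the one additive
exception is the flag for cross-sectional market-research/quota samples, whose
pre-pandemic baseline came from a different (random) sample and which can
therefore shift prevalence even at zero impact. Candidate covariates are
removed by backward elimination under the Akaike information criterion.

Estimation maximises the marginal likelihood of the normal–normal hierarchical
model; fixed-effect uncertainty is propagated as 1000 seeded draws from the
asymptotic multivariate normal at the optimum, and 95% uncertainty intervals
are the 25th and 975th ranked draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CoefficientSet",
    "delta_logit",
    "transform_exposures",
    "build_model_frame",
    "fit_indicator_model",
    "compute_impact_index",
    "fit_final_model",
    "predict_logit_shift",
    "combined_indicator_coefficients",
]

INDICATOR_NAMES = ("mobility_decrease", "sqrt_infection", "sqrt_excess")

#: effect-modifier covariates of the final model (they multiply the index)
MODIFIER_NAMES = ("mean_age", "prop_female", "combined_symptoms",
                  "cs_random", "long_quota")
#: additive bias covariates of the final model
ADDITIVE_NAMES = ("cs_quota",)

DEFAULT_DRAWS = 1000


# ---------------------------------------------------------------------------
# outcome construction
# ---------------------------------------------------------------------------

def delta_logit(prev_pre, prev_mid, n_pre, n_mid, continuity=False):
    """Logit prevalence difference and its delta-method standard error.

    Returns ``(delta, se)`` with ``delta = logit(prev_mid) - logit(prev_pre)``
    and ``se^2 = 1/(n_pre p_pre (1-p_pre)) + 1/(n_mid p_mid (1-p_mid))``.

    Boundary prevalences (exactly 0 or 1) are rejected unless ``continuity``
    is set, in which case half a case is added to the numerator and one
    observation to the denominator of the offending wave.
    """
    p0, p1 = float(prev_pre), float(prev_mid)
    n0, n1 = float(n_pre), float(n_mid)
    if n0 < 1 or n1 < 1:
        raise ValueError("sample sizes must be >= 1")
    if continuity:
        if p0 <= 0.0 or p0 >= 1.0:
            p0 = (p0 * n0 + 0.5) / (n0 + 1.0)
        if p1 <= 0.0 or p1 >= 1.0:
            p1 = (p1 * n1 + 0.5) / (n1 + 1.0)
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ValueError(
            f"prevalence at the 0/1 boundary (pre={prev_pre}, mid={prev_mid}) "
            "and no continuity correction enabled"
        )
    delta = special.logit(p1) - special.logit(p0)
    var = 1.0 / (n0 * p0 * (1.0 - p0)) + 1.0 / (n1 * p1 * (1.0 - p1))
    return delta, float(np.sqrt(var))


def transform_exposures(mobility_decrease, infection_rate, excess_mortality_rate):
    """Square-root transform the two rate indicators (positive skew); mobility
    enters untransformed. Returns an array/DataFrame-compatible tuple."""
    mob = np.asarray(mobility_decrease, dtype=float)
    inf = np.asarray(infection_rate, dtype=float)
    exc = np.asarray(excess_mortality_rate, dtype=float)
    if np.any(inf < 0) or np.any(exc < 0):
        raise ValueError("rates must be nonnegative before square-root transform")
    return mob, np.sqrt(inf), np.sqrt(exc)


def build_model_frame(studies: pd.DataFrame, indicators: pd.DataFrame,
                      continuity: bool = False) -> pd.DataFrame:
    """Assemble the per-observation regression frame from study records and
    daily indicator series.

    Exposures are the daily transformed indicators averaged over each study's
    mid-pandemic window. Design flags are dummies against the
    longitudinal-random reference.
    """
    ind = indicators.copy()
    ind["date"] = pd.to_datetime(ind["date"])
    mob, sqi, sqe = transform_exposures(
        ind["mobility_decrease"], ind["infection_rate"], ind["excess_mortality_rate"])
    ind["_mob"], ind["_sqi"], ind["_sqe"] = mob, sqi, sqe
    by_loc = {loc: g.set_index("date") for loc, g in ind.groupby("location_id")}

    rows = []
    for rec in studies.itertuples(index=False):
        d, se = delta_logit(rec.prev_pre, rec.prev_mid, rec.n_pre, rec.n_mid,
                            continuity=continuity)
        loc = rec.location_id
        if loc not in by_loc:
            raise ValueError(f"no indicator series for location {loc!r}")
        g = by_loc[loc]
        start, end = pd.Timestamp(rec.mid_start), pd.Timestamp(rec.mid_end)
        win = g.loc[(g.index >= start) & (g.index <= end)]
        if win.empty:
            raise ValueError(
                f"no indicator coverage for location {loc!r} in window "
                f"{start.date()}..{end.date()}")
        rows.append({
            "sample_id": rec.sample_id,
            "location_id": loc,
            "disorder": rec.disorder,
            "delta_logit": d,
            "se_delta": se,
            "mobility_decrease": win["_mob"].mean(),
            "sqrt_infection": win["_sqi"].mean(),
            "sqrt_excess": win["_sqe"].mean(),
            "mean_age": rec.mean_age,
            "prop_female": rec.prop_female,
            "combined_symptoms": float(rec.combined_symptoms),
            "cs_random": float(rec.design == "cross_sectional_random"),
            "long_quota": float(rec.design == "longitudinal_quota"),
            "cs_quota": float(rec.design == "cross_sectional_quota"),
        })
    frame = pd.DataFrame(rows)
    if not np.all(frame["se_delta"] > 0) or not np.all(np.isfinite(frame["delta_logit"])):
        raise ValueError("invalid outcome: se_delta must be > 0 and delta_logit finite")
    return frame


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class CoefficientSet:
    """Fixed-effect draws plus random-effect variances from one fitted model."""

    disorder: str
    names: list
    beta: np.ndarray               # point estimates, shape (p,)
    cov: np.ndarray                # asymptotic covariance of beta, (p, p)
    draws: np.ndarray              # (n_draws, p) seeded posterior draws
    re_var_intercept: float
    re_var_indicator: float
    roles: dict                    # covariate name -> indicator|index|modifier|additive_bias
    pvalues: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    elimination_log: list = field(default_factory=list)

    def _idx(self, name: str) -> int:
        return self.names.index(name)

    def draws_for(self, name: str) -> np.ndarray:
        return self.draws[:, self._idx(name)]

    def p_for(self, name: str) -> float:
        return float(self.pvalues[self._idx(name)])

    def summary(self) -> pd.DataFrame:
        from .adjust import ui_summary
        recs = []
        for j, name in enumerate(self.names):
            s = ui_summary(self.draws[:, j], expected=None)
            recs.append({"covariate": name, "role": self.roles[name],
                         "mean": s.mean, "lower": s.lower, "upper": s.upper,
                         "p": float(self.pvalues[j])})
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# hierarchical normal-normal estimation core
# ---------------------------------------------------------------------------

def _group_indices(groups):
    codes, _ = pd.factorize(np.asarray(groups))
    return [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]


def _check_design(X, names):
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0.0 and np.all(X[:, j] == 0.0):
            raise ValueError(f"degenerate design column {name!r}: all values are zero")


def _parts(y, se2, X, Z, gidx, tau2cols):
    """Accumulate X'V^-1 X, X'V^-1 y, y'V^-1 y and sum log|V| over groups."""
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for idx in gidx:
        Xg, yg = X[idx], y[idx]
        V = np.diag(se2[idx])
        if Z is not None and np.any(tau2cols > 0):
            Zg = Z[idx]
            V = V + (Zg * tau2cols) @ Zg.T
        L = np.linalg.cholesky(V)
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        Xs = np.linalg.solve(L, Xg) if Xg.size else Xg
        ys = np.linalg.solve(L, yg)
        XtViX += Xs.T @ Xs
        XtViy += Xs.T @ ys
        ytViy += ys @ ys
    return XtViX, XtViy, ytViy, logdet


def _gls_constrained(XtViX, XtViy, sign):
    """GLS solve with an active-set treatment of sign constraints.

    ``sign[k]`` in {0, +1, -1}: 0 unconstrained, +1 requires beta_k >= 0,
    -1 requires beta_k <= 0. Violating coefficients are pinned at 0.
    """
    p = len(XtViy)
    active = np.zeros(p, dtype=bool)
    for _ in range(p + 1):
        free = ~active
        beta = np.zeros(p)
        beta[free] = np.linalg.solve(XtViX[np.ix_(free, free)], XtViy[free])
        viol = (sign != 0) & free & (sign * beta < 0)
        if not viol.any():
            return beta, active
        active |= viol
    return beta, active  # pragma: no cover


def _fit_mixed(y, se, X, names, Z, tau_map, groups, *, sign=None,
               fix_tau=None, n_draws=DEFAULT_DRAWS, seed=0, disorder="",
               roles=None, method="reml"):
    """Marginal-likelihood fit of delta ~ N(X beta, diag(se^2) + Z D Z').

    tau_map maps each Z column to one of the (at most two) free variance
    parameters: 0 = random-intercept variance, 1 = shared indicator-slope
    variance. ``fix_tau`` pins a variance parameter (e.g. to 0).

    ``method='reml'`` (default) maximises the restricted likelihood for the
    variance components — the standard meta-analytic choice, which avoids the
    downward ML bias in tau^2 and the resulting anti-conservative fixed-effect
    intervals; ``'ml'`` maximises the ordinary marginal likelihood. The
    reported loglik/AIC are always the ordinary marginal values at the
    optimum, so AICs stay comparable across fixed-effect specifications.
    """
    y = np.asarray(y, float)
    se2 = np.asarray(se, float) ** 2
    X = np.asarray(X, float)
    n, p = X.shape
    _check_design(X, names)
    sign = np.zeros(p) if sign is None else np.asarray(sign, float)
    gidx = _group_indices(groups)
    if len(gidx) < 2:
        raise ValueError("need >= 2 distinct sample_ids to fit random effects")

    n_tau = 0 if tau_map is None else int(np.max(tau_map)) + 1
    fixed = dict(fix_tau or {})
    free_tau = [k for k in range(n_tau) if k not in fixed]

    def tau2cols(tau2_free):
        full = np.zeros(n_tau)
        for k in range(n_tau):
            full[k] = fixed[k] if k in fixed else tau2_free[free_tau.index(k)]
        return full[np.asarray(tau_map)] if n_tau else None

    def profile_nll(sds):
        t2 = tau2cols(np.asarray(sds, float) ** 2)
        XtViX, XtViy, ytViy, logdet = _parts(y, se2, X, Z, gidx, t2)
        beta, _ = _gls_constrained(XtViX, XtViy, sign)
        quad = ytViy - 2.0 * beta @ XtViy + beta @ XtViX @ beta
        nll = 0.5 * (logdet + quad + n * np.log(2.0 * np.pi))
        if method == "reml":
            nll += 0.5 * np.linalg.slogdet(XtViX)[1]
        return nll

    if free_tau:
        x0 = np.full(len(free_tau), 0.1)
        res = optimize.minimize(profile_nll, x0, method="Nelder-Mead",
                                bounds=[(0.0, 50.0)] * len(free_tau),
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        sds_hat = np.abs(res.x)
    else:
        sds_hat = np.zeros(0)

    t2 = tau2cols(sds_hat ** 2)
    XtViX, XtViy, ytViy, logdet = _parts(y, se2, X, Z, gidx, t2)
    beta, active = _gls_constrained(XtViX, XtViy, sign)
    quad = ytViy - 2.0 * beta @ XtViy + beta @ XtViX @ beta
    loglik = -0.5 * (logdet + quad + n * np.log(2.0 * np.pi))
    try:
        cov = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular design matrix ({names})") from err

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(beta, cov, size=n_draws, method="svd")
    for k in range(p):
        if sign[k] > 0:
            draws[:, k] = np.maximum(draws[:, k], 0.0)
        elif sign[k] < 0:
            draws[:, k] = np.minimum(draws[:, k], 0.0)

    mean, sd = draws.mean(axis=0), draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, np.abs(mean) / sd, np.where(mean == 0, 0.0, np.inf))
    pvals = 2.0 * stats.norm.sf(z)

    def tau_value(k):
        if n_tau <= k:
            return 0.0
        return float(fixed[k]) if k in fixed else float(sds_hat[free_tau.index(k)] ** 2)

    k_params = p + len(free_tau)
    return CoefficientSet(
        disorder=disorder, names=list(names), beta=beta, cov=cov, draws=draws,
        re_var_intercept=tau_value(0), re_var_indicator=tau_value(1),
        roles=roles or {}, pvalues=pvals, loglik=float(loglik),
        aic=float(2.0 * k_params - 2.0 * loglik), n_obs=n,
    )


# ---------------------------------------------------------------------------
# step one: indicator model and impact index
# ---------------------------------------------------------------------------

def fit_indicator_model(frame: pd.DataFrame, *, disorder: str = "",
                        excess_direction: str = "nonnegative",
                        trim: float = 0.0, n_draws: int = DEFAULT_DRAWS,
                        seed: int = 0, fix_tau: dict | None = None,
                        bias_covariates: tuple = ADDITIVE_NAMES,
                        method: str = "reml") -> CoefficientSet:
    """Step-one meta-regression of delta_logit on the three transformed
    indicators simultaneously (no global intercept).

    Random intercept per sample_id plus a shared-variance random slope on each
    indicator; the excess-mortality coefficient is fitted under a directional
    prior (default: nonnegative) because of its collinearity with the other
    indicators. The additive quota-sample bias flag is controlled for here
    too (it shifts prevalence even at zero impact, and leaving it out would
    swamp the random-intercept variance); bias covariates never enter the
    impact index. ``trim`` optionally drops the worst fraction of
    observations by standardised marginal residual after an initial fit
    (default off).
    """
    names = list(INDICATOR_NAMES)
    bias = [b for b in bias_covariates
            if b in frame.columns and np.ptp(frame[b].to_numpy(float)) > 0.0]
    X = frame[names + bias].to_numpy(float)
    Zind = frame[names].to_numpy(float)
    Z = np.column_stack([np.ones(len(frame)), Zind])
    tau_map = np.array([0, 1, 1, 1])
    sign = {"nonnegative": [0, 0, 1.0], "nonpositive": [0, 0, -1.0],
            "none": [0, 0, 0]}[excess_direction] + [0.0] * len(bias)
    roles = {n: "indicator" for n in names}
    roles.update({b: "additive_bias" for b in bias})
    names = names + bias
    kw = dict(sign=sign, fix_tau=fix_tau, n_draws=n_draws, seed=seed,
              disorder=disorder, roles=roles, method=method)

    fit = _fit_mixed(frame["delta_logit"], frame["se_delta"], X, names, Z,
                     tau_map, frame["sample_id"], **kw)
    if trim > 0.0:
        resid = frame["delta_logit"].to_numpy() - X @ fit.beta
        marg_sd = np.sqrt(frame["se_delta"].to_numpy() ** 2
                          + fit.re_var_intercept
                          + fit.re_var_indicator * (Zind ** 2).sum(axis=1))
        keep = np.argsort(-np.abs(resid / marg_sd))[int(np.ceil(trim * len(frame))):]
        sub = frame.iloc[np.sort(keep)]
        Xs = sub[names].to_numpy(float)
        Zs = np.column_stack([np.ones(len(sub)),
                              sub[list(INDICATOR_NAMES)].to_numpy(float)])
        fit = _fit_mixed(sub["delta_logit"], sub["se_delta"], Xs, names,
                         Zs, tau_map, sub["sample_id"], **kw)
    return fit


def retained_indicators(coeffs: CoefficientSet, p_threshold: float = 0.05):
    """Indicator covariates significant at ``p_threshold`` (the ones that
    enter the impact index)."""
    return [n for n in coeffs.names
            if coeffs.roles.get(n) == "indicator" and coeffs.p_for(n) < p_threshold]


def compute_impact_index(exposure, coeffs: CoefficientSet, *,
                         p_threshold: float = 0.05, per_draw: bool = True):
    """Collapse the significant step-one coefficients and the transformed
    exposures into the scalar COVID-19 impact index.

    ``exposure`` is a mapping (or DataFrame) with keys among
    ``mobility_decrease / sqrt_infection / sqrt_excess``; values may be
    scalars or arrays. Returns, for per_draw=True, an array with a trailing
    draw axis; otherwise the point-coefficient index with the exposure's
    shape. Zero exposure gives exactly zero index.
    """
    kept = retained_indicators(coeffs, p_threshold)
    xs = {n: np.asarray(exposure[n], dtype=float) for n in kept}
    base = np.zeros(np.broadcast_shapes(*(x.shape for x in xs.values())) or ())
    if per_draw:
        out = base[..., None] * np.zeros(coeffs.draws.shape[0])
        for n in kept:
            out = out + xs[n][..., None] * coeffs.draws_for(n)
    else:
        out = base.copy()
        for n in kept:
            out = out + xs[n] * coeffs.beta[coeffs._idx(n)]
    return out


# ---------------------------------------------------------------------------
# step two: final model with effect modifiers
# ---------------------------------------------------------------------------

def _final_design(frame: pd.DataFrame, index: np.ndarray, covariates):
    cols, names = [np.asarray(index, float)], ["index"]
    for c in covariates:
        if c in MODIFIER_NAMES:
            cols.append(frame[c].to_numpy(float) * index)
        elif c in ADDITIVE_NAMES:
            cols.append(frame[c].to_numpy(float))
        else:
            raise ValueError(f"unknown final-model covariate {c!r}")
        names.append(c)
    return np.column_stack(cols), names


def fit_final_model(frame: pd.DataFrame, index, *, candidates=None,
                    disorder: str = "", n_draws: int = DEFAULT_DRAWS,
                    seed: int = 0, fix_tau: dict | None = None,
                    eliminate: bool = True, method: str = "reml") -> CoefficientSet:
    """Step-two model with AIC backward elimination.

    The impact index is always retained; candidate effect modifiers and the
    additive quota-bias flag are dropped one at a time (least significant
    first) while the AIC improves. Ties on p-value are broken by the smaller
    absolute standardised coefficient. Returns the final fit with an
    ``elimination_log`` of ``(dropped, aic_before, aic_after)`` steps.
    ``eliminate=False`` fits the full candidate set (used by the recovery
    harness, where shrinking a weakly identified truth to an eliminated 0
    would confound bias measurement with selection).
    """
    index = np.broadcast_to(np.asarray(index, float),
                            (len(frame),)).astype(float)
    if candidates is None:
        candidates = [c for c in MODIFIER_NAMES + ADDITIVE_NAMES
                      if c in frame.columns and np.ptp(frame[c].to_numpy(float)) > 0
                      or c in ("mean_age", "prop_female")]
    candidates = list(candidates)
    Zcols = np.column_stack([np.ones(len(frame)), index])
    tau_map = np.array([0, 1])

    def fit_with(covs):
        X, names = _final_design(frame, index, covs)
        roles = {"index": "index"}
        roles.update({c: ("modifier" if c in MODIFIER_NAMES else "additive_bias")
                      for c in covs})
        return _fit_mixed(frame["delta_logit"], frame["se_delta"], X, names,
                          Zcols, tau_map, frame["sample_id"], fix_tau=fix_tau,
                          n_draws=n_draws, seed=seed, disorder=disorder,
                          roles=roles, method=method)

    current = fit_with(candidates)
    log = []
    covs = candidates
    while covs and eliminate:
        ps = np.array([current.p_for(c) for c in covs])
        std = np.array([abs(current.beta[current._idx(c)])
                        / np.sqrt(current.cov[current._idx(c), current._idx(c)])
                        for c in covs])
        order = np.lexsort((std, -ps))  # highest p first, smaller |z| breaks ties
        worst = covs[order[0]]
        reduced = fit_with([c for c in covs if c != worst])
        if reduced.aic < current.aic:
            log.append({"dropped": worst, "aic_before": current.aic,
                        "aic_after": reduced.aic})
            current, covs = reduced, [c for c in covs if c != worst]
        else:
            break
    current.elimination_log = log
    return current


def predict_logit_shift(index, coeffs: CoefficientSet, *, mean_age=0.0,
                        prop_female=0.0, combined_symptoms=0.0, cs_random=0.0,
                        long_quota=0.0, cs_quota=0.0, per_draw: bool = True,
                        index_has_draw_axis: bool = False):
    """Predicted change in logit prevalence from the final model.

    ``shift = (b_index + b_age*age + b_sex*pf + ...) * index + b_cs_quota*flag``
    using whichever covariates survived elimination. Bias flags default to the
    reference level (0) for population prediction, so zero impact always gives
    zero shift. ``index`` may be a scalar or array; with per_draw a trailing
    draw axis is appended. If the index itself was computed per draw (its last
    axis is already the draw axis), set ``index_has_draw_axis`` so draw d of
    the index pairs with coefficient draw d (common random numbers).
    """
    index = np.asarray(index, float)
    vals = {"mean_age": mean_age, "prop_female": prop_female,
            "combined_symptoms": combined_symptoms, "cs_random": cs_random,
            "long_quota": long_quota, "cs_quota": cs_quota}

    def coef(name):
        if name not in coeffs.names:
            return None
        return coeffs.draws_for(name) if per_draw else coeffs.beta[coeffs._idx(name)]

    mod = coef("index")
    if mod is None:
        raise ValueError("coefficient set has no 'index' term; not a final model")
    mod = np.asarray(mod, float)
    add = np.zeros_like(mod)
    for name in MODIFIER_NAMES:
        b = coef(name)
        if b is not None:
            mod = mod + b * vals[name]
    for name in ADDITIVE_NAMES:
        b = coef(name)
        if b is not None:
            add = add + b * vals[name]
    if per_draw and not index_has_draw_axis:
        return index[..., None] * mod + add
    return index * mod + add


def combined_indicator_coefficients(index_coeffs: CoefficientSet,
                                    final_coeffs: CoefficientSet,
                                    p_threshold: float = 0.05) -> dict:
    """Per-indicator combined coefficients: elementwise product of the
    step-one indicator draws with the step-two index-coefficient draws."""
    b_index = final_coeffs.draws_for("index")
    out = {}
    for name in retained_indicators(index_coeffs, p_threshold):
        d = index_coeffs.draws_for(name)
        if d.shape != b_index.shape:
            raise ValueError(
                f"draw-count mismatch: {d.shape[0]} indicator draws vs "
                f"{b_index.shape[0]} index draws")
        out[name] = d * b_index
    return out
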