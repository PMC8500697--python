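"""Draw-based adjustment of baseline prevalence surfaces.

For every draw d and day t, the baseline prevalence draw p_d of a
disorder x location x age x sex cell is moved on the logit scale by the
predicted shift for that day and inverse-logit transformed:

    p_d(t) = invlogit( logit(p_d) + shift_d(t) )

The annual point prevalence is the per-draw arithmetic mean of the daily
series over the whole year (days before the location's pandemic start carry
zero shift and are included). All summaries are ranked-draw: the 95%
uncertainty interval is the 25th and 975th ranked of the 1000 draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .metareg import CoefficientSet, compute_impact_index, predict_logit_shift

__all__ = [
    "UISummary",
    "ui_summary",
    "daily_adjusted_prevalence",
    "annual_point_prevalence",
    "adjust_surfaces",
    "change_accounting",
]


@dataclass(frozen=True)
class UISummary:
    mean: float
    lower: float   # 25th ranked draw (of 1000)
    upper: float   # 975th ranked draw


def ui_summary(draws, expected: int | None = 1000) -> UISummary:
    """Mean and ranked-draw 95% uncertainty interval.

    With 1000 draws the bounds are exactly the 25th and 975th ranked values
    (1-based, ascending); other draw counts use the same 2.5%/97.5% ranks.
    ``expected`` enforces the draw count (pass None to accept any n >= 2).
    """
    x = np.asarray(draws, dtype=float).ravel()
    if expected is not None and x.size != expected:
        raise ValueError(f"expected {expected} draws, got {x.size}")
    if x.size < 2:
        raise ValueError("need at least 2 draws to summarise")
    if not np.all(np.isfinite(x)):
        raise ValueError("draws must all be finite")
    s = np.sort(x)
    k_lo = max(int(round(0.025 * x.size)), 1)
    k_hi = min(int(round(0.975 * x.size)), x.size)
    return UISummary(mean=float(x.mean()), lower=float(s[k_lo - 1]),
                     upper=float(s[k_hi - 1]))


def daily_adjusted_prevalence(baseline_draws, shift_draws, cell: str = ""):
    """Apply per-draw logit shifts to baseline prevalence draws.

    ``baseline_draws``: (n_draws,) proportions strictly inside (0, 1).
    ``shift_draws``: (n_draws,) or (n_days, n_draws). Returns the same shape
    as ``shift_draws`` broadcast against the baseline, strictly inside (0, 1).
    """
    p = np.asarray(baseline_draws, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError(f"baseline prevalence draw at the 0/1 boundary"
                         f"{' in cell ' + cell if cell else ''}")
    shift = np.asarray(shift_draws, dtype=float)
    out = special.expit(special.logit(p) + shift)
    # zero-shift days (pre-pandemic) reproduce the baseline exactly, not up
    # to expit/logit round-trip error
    return np.where(shift == 0.0, np.broadcast_to(p, out.shape), out)


def annual_point_prevalence(daily_draws):
    """Per-draw arithmetic mean over days; daily_draws is (n_days, n_draws)."""
    arr = np.asarray(daily_draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a (n_days, n_draws) array with at least one day")
    return arr.mean(axis=0)


def adjust_surfaces(surfaces: pd.DataFrame, indicators: pd.DataFrame,
                    index_coeffs: CoefficientSet, final_coeffs: CoefficientSet,
                    p_threshold: float = 0.05) -> pd.DataFrame:
    """Adjust every baseline surface cell over the full daily indicator series.

    ``surfaces`` rows hold disorder/location_id/age_lo/age_hi/sex plus draw_*
    columns; ``indicators`` is the daily series for all locations. Prediction
    uses the cell's age midpoint, prop_female in {0,1} and bias flags at
    reference. Returns a frame with baseline/final/additional draw columns.
    """
    from .metareg import transform_exposures

    n_draws = index_coeffs.draws.shape[0]
    draw_cols = [c for c in surfaces.columns if c.startswith("draw_")]
    if len(draw_cols) != n_draws:
        raise ValueError(f"surface has {len(draw_cols)} draws, "
                         f"coefficients have {n_draws}")

    # per-location (n_days, n_draws) index, shared by all cells of the location
    loc_index = {}
    for loc, g in indicators.groupby("location_id"):
        g = g.sort_values("date")
        mob, sqi, sqe = transform_exposures(
            g["mobility_decrease"], g["infection_rate"], g["excess_mortality_rate"])
        loc_index[loc] = compute_impact_index(
            {"mobility_decrease": mob, "sqrt_infection": sqi, "sqrt_excess": sqe},
            index_coeffs, p_threshold=p_threshold, per_draw=True)

    out_rows = []
    for rec in surfaces.itertuples(index=False):
        loc = rec.location_id
        if loc not in loc_index:
            raise ValueError(f"no indicator series for location {loc!r}")
        base = np.array([getattr(rec, c) for c in draw_cols], dtype=float)
        age_mid = 0.5 * (rec.age_lo + rec.age_hi)
        pf = 1.0 if rec.sex == "female" else 0.0
        shift = predict_logit_shift(loc_index[loc], final_coeffs,
                                    mean_age=age_mid, prop_female=pf,
                                    index_has_draw_axis=True)
        daily = daily_adjusted_prevalence(
            base, shift, cell=f"{rec.disorder}/{loc}/{rec.age_lo}-{rec.age_hi}/{rec.sex}")
        final = annual_point_prevalence(daily)
        row = {"disorder": rec.disorder, "location_id": loc,
               "age_lo": rec.age_lo, "age_hi": rec.age_hi, "sex": rec.sex}
        row.update({f"baseline_{c}": v for c, v in zip(draw_cols, base)})
        row.update({f"final_{c}": v for c, v in zip(draw_cols, final)})
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    add = pd.DataFrame(
        {f"additional_{c}": out[f"final_{c}"] - out[f"baseline_{c}"]
         for c in draw_cols})
    return pd.concat([out, add], axis=1)


def _summ(prefix: str, draws: np.ndarray) -> dict:
    s = ui_summary(draws, expected=None)
    return {f"{prefix}_mean": s.mean, f"{prefix}_lower": s.lower,
            f"{prefix}_upper": s.upper}


def change_accounting(adjusted: pd.DataFrame, populations: pd.DataFrame,
                      per_100k: float = 1e5,
                      group_cols=("disorder",)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline/additional/final rates, percent change and case counts.

    Returns ``(per_cell, aggregated)`` tables. Rates are per 100 000;
    ``percent change`` per draw is 100*additional/baseline; aggregation is
    population-weighted across cells per draw, then summarised from the
    aggregated draws. Both the mean of per-draw ratios and the ratio of mean
    rates are emitted (``pct_change_mean`` and ``pct_change_of_means``); the
    latter matches arithmetic done on published summary rows. The identity
    final = baseline + additional holds per draw by construction.
    """
    cell_keys = ["disorder", "location_id", "age_lo", "age_hi", "sex"]
    pop_keys = [k for k in cell_keys if k in populations.columns and k != "disorder"]
    merged = adjusted.merge(populations[pop_keys + ["population"]],
                            on=pop_keys, how="left", validate="many_to_one")
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna(), cell_keys].iloc[0]
        raise ValueError(f"missing population for cell {bad.to_dict()}")

    draw_ids = sorted(int(c.split("_")[-1]) for c in adjusted.columns
                      if c.startswith("baseline_draw_"))
    base = merged[[f"baseline_draw_{i}" for i in draw_ids]].to_numpy(float)
    fin = merged[[f"final_draw_{i}" for i in draw_ids]].to_numpy(float)
    add = fin - base
    pop = merged["population"].to_numpy(float)

    per_cell = merged[cell_keys + ["population"]].copy()
    for name, arr in (("baseline", base), ("additional", add), ("final", fin)):
        r = arr * per_100k
        per_cell[f"{name}_rate_mean"] = r.mean(axis=1)
        per_cell[f"{name}_count_mean"] = (arr * pop[:, None]).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cell["pct_change_mean"] = (100.0 * add / base).mean(axis=1)

    groups = []
    gcols = list(group_cols)
    for key, g in merged.groupby(gcols):
        key = key if isinstance(key, tuple) else (key,)
        idx = g.index.to_numpy()
        w = pop[idx]
        wsum = w.sum()
        gb = (base[idx] * w[:, None]).sum(axis=0) / wsum
        gf = (fin[idx] * w[:, None]).sum(axis=0) / wsum
        ga = gf - gb
        row = dict(zip(gcols, key))
        row["population"] = wsum
        row.update(_summ("baseline_rate", gb * per_100k))
        row.update(_summ("additional_rate", ga * per_100k))
        row.update(_summ("final_rate", gf * per_100k))
        row.update(_summ("pct_change", 100.0 * ga / gb))
        row["pct_change_of_means"] = 100.0 * ga.mean() / gb.mean()
        row.update(_summ("additional_count", ga * wsum))
        row.update(_summ("final_count", gf * wsum))
        groups.append(row)
    return per_cell, pd.DataFrame(groups)
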