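"""Severity splits, disability weights, YLDs and DALYs.

Prevalence of each disorder is apportioned into asymptomatic / mild /
moderate / severe health states with fixed proportions; years lived with
disability (YLD) are the prevalence-weighted sum of the states' disability
weights. Major depressive disorder and anxiety disorders carry no years of
life lost in this framework, so DALYs equal YLDs exactly, draw by draw.

Baseline (counterfactual, no-pandemic) burden is obtained by rescaling the
adjusted burden by the per-draw ratio of baseline to final prevalence, the
same ratio adjustment used to back out pre-pandemic burden from a
pandemic-adjusted burden pipeline. The full-cause comorbidity correction is
out of scope and replaced by an optional scalar multiplier (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import ui_summary

__all__ = ["SeverityInputs", "severity_split", "ylds",
           "baseline_burden_rescale", "burden_table"]

SEVERITIES = ("asymptomatic", "mild", "moderate", "severe")


@dataclass(frozen=True)
class SeverityInputs:
    disorder: str
    proportions: dict   # severity -> fraction, summing to 1
    weights: dict       # severity -> disability weight in [0, 1]

    def validate(self):
        total = sum(self.proportions[s] for s in SEVERITIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"severity proportions sum to {total}, not 1")
        if self.weights.get("asymptomatic", 0.0) != 0.0:
            raise ValueError("asymptomatic disability weight must be 0")
        for s in SEVERITIES:
            w = self.weights[s]
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"disability weight for {s!r} outside [0,1]: {w}")
        return self


def severity_split(prevalence_draws, severity: SeverityInputs) -> dict:
    """Multiplicative apportioning of total prevalence into severity states.

    The state-specific prevalences sum back to the total to 1e-12.
    """
    severity.validate()
    p = np.asarray(prevalence_draws, dtype=float)
    return {s: p * severity.proportions[s] for s in SEVERITIES}


def ylds(severity_prevalence: dict, weights: dict,
         comorbidity_scalar: float = 1.0):
    """YLD rate draws: sum over severities of prevalence x disability weight,
    optionally scaled by a comorbidity multiplier."""
    for s, w in weights.items():
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"disability weight for {s!r} outside [0,1]: {w}")
    out = None
    for s, prev in severity_prevalence.items():
        term = np.asarray(prev, dtype=float) * weights[s]
        out = term if out is None else out + term
    return out * comorbidity_scalar


def baseline_burden_rescale(adjusted_burden_draws, baseline_prev_draws,
                            final_prev_draws):
    """Counterfactual baseline burden: adjusted burden times the per-draw
    ratio of baseline to final (adjusted) prevalence."""
    fin = np.asarray(final_prev_draws, dtype=float)
    if np.any(fin <= 0.0):
        raise ValueError("final prevalence draw of zero; ratio rescale undefined")
    return (np.asarray(adjusted_burden_draws, dtype=float)
            * np.asarray(baseline_prev_draws, dtype=float) / fin)


def burden_table(adjusted: pd.DataFrame, severity_by_disorder: dict,
                 populations: pd.DataFrame, comorbidity_scalar: float = 1.0,
                 per_100k: float = 1e5) -> pd.DataFrame:
    """Per-cell YLD/DALY rates and counts with ranked-draw UIs.

    ``adjusted`` is the output of :func:`mhshock.adjust.adjust_surfaces`.
    Emits adjusted (final), baseline (ratio-rescaled) and additional burden;
    DALY columns equal YLD columns exactly (no YLL component).
    """
    draw_ids = sorted(int(c.split("_")[-1]) for c in adjusted.columns
                      if c.startswith("final_draw_"))
    fcols = [f"final_draw_{i}" for i in draw_ids]
    bcols = [f"baseline_draw_{i}" for i in draw_ids]
    pop_keys = [k for k in ("location_id", "age_lo", "age_hi", "sex")
                if k in populations.columns]
    merged = adjusted.merge(populations[pop_keys + ["population"]],
                            on=pop_keys, how="left", validate="many_to_one")
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna()].iloc[0]
        raise ValueError(f"missing population for cell "
                         f"{bad[['location_id', 'age_lo', 'sex']].to_dict()}")

    rows = []
    for rec in merged.itertuples(index=False):
        sev = severity_by_disorder[rec.disorder].validate()
        fin = np.array([getattr(rec, c) for c in fcols], dtype=float)
        base = np.array([getattr(rec, c) for c in bcols], dtype=float)
        yld_fin = ylds(severity_split(fin, sev), sev.weights, comorbidity_scalar)
        yld_base = baseline_burden_rescale(yld_fin, base, fin)
        yld_add = yld_fin - yld_base
        row = {"disorder": rec.disorder, "location_id": rec.location_id,
               "age_lo": rec.age_lo, "age_hi": rec.age_hi, "sex": rec.sex,
               "population": rec.population}
        for name, arr in (("yld_final", yld_fin), ("yld_baseline", yld_base),
                          ("yld_additional", yld_add)):
            s = ui_summary(arr * per_100k, expected=None)
            row[f"{name}_rate_mean"] = s.mean
            row[f"{name}_rate_lower"] = s.lower
            row[f"{name}_rate_upper"] = s.upper
            row[f"{name}_count_mean"] = float((arr * rec.population).mean())
            # DALYs for these disorders are composed entirely of YLDs
            row[name.replace("yld", "daly") + "_rate_mean"] = s.mean
            row[name.replace("yld", "daly") + "_rate_lower"] = s.lower
            row[name.replace("yld", "daly") + "_rate_upper"] = s.upper
            row[name.replace("yld", "daly") + "_count_mean"] = \
                float((arr * rec.population).mean())
        rows.append(row)
    return pd.DataFrame(rows)
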