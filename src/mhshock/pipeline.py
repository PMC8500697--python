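"""End-to-end pipeline driver.

Stages: simulate (optional fixture generation) -> fit (two-step
meta-regression per disorder) -> adjust (daily draw-level prevalence
adjustment, annual averaging, change accounting) -> burden (severity splits,
YLDs, DALYs) -> validate (leave-one-country-out). Every stage reads the
previous stage's tables from the output directory, so each is runnable
standalone; all randomness flows from a single root seed expanded per stage.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjust as adjust_mod
from . import burden as burden_mod
from . import io, metareg, synthdata, validate as validate_mod

log = logging.getLogger("mhshock")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[mhshock:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage, msg):
    log.info(msg, extra={"stage": stage})


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    draws: int = 1000
    disorders: tuple = ("MDD", "anxiety")
    # input paths; None means "use the simulate stage's outputs in out_dir"
    indicators_path: str | None = None
    studies_path: str | None = None
    baseline_path: str | None = None
    populations_path: str | None = None
    severity_path: str | None = None
    comorbidity_scalar: float = 1.0
    excess_direction: str = "nonnegative"
    trim: float = 0.0
    p_threshold: float = 0.05
    synthetic: synthdata.SyntheticConfig | None = None

    def __post_init__(self):
        if self.draws < 2:
            raise ValueError("draw count must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a pipeline config from YAML. A nested ``synthetic:`` block
        becomes the generator config; a ``metareg:`` block maps onto the
        estimation options (excess_direction, trim, p_threshold)."""
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        metareg_opts = raw.pop("metareg", {})
        for k in ("excess_direction", "trim", "p_threshold"):
            if k in metareg_opts:
                raw[k] = metareg_opts[k]
        if "disorders" in raw:
            raw["disorders"] = tuple(raw["disorders"])
        cfg = cls(**raw)
        if syn:
            if "disorders" in syn:
                syn["disorders"] = tuple(syn["disorders"])
            cfg.synthetic = synthdata.SyntheticConfig(**syn)
        return cfg

    def path(self, name: str, default: str) -> Path:
        explicit = getattr(self, name, None)
        p = Path(explicit) if explicit else Path(self.out_dir) / default
        return p

    def require(self, name: str, default: str) -> Path:
        p = self.path(name, default)
        if not p.exists():
            raise FileNotFoundError(f"required input not found: {p}")
        return p


def stage_simulate(cfg: PipelineConfig) -> dict:
    syn = cfg.synthetic or synthdata.SyntheticConfig(
        seed=cfg.seed, n_draws=cfg.draws, disorders=cfg.disorders)
    out = Path(cfg.out_dir)
    _stage_log("simulate", f"generating synthetic inputs (seed={syn.seed}, "
               f"{syn.n_locations} locations, {syn.n_studies} studies/disorder)")
    indicators = synthdata.generate_indicators(syn)
    surfaces, populations, severity = synthdata.generate_baseline(syn)
    studies, truth = synthdata.generate_surveys(syn, indicators, surfaces)
    paths = {
        "indicators": io.write_csv(indicators, out / "indicators.csv"),
        "studies": io.write_csv(studies, out / "studies.csv"),
        "baseline": io.write_csv(surfaces, out / "baseline_prevalence.csv"),
        "populations": io.write_csv(populations, out / "populations.csv"),
        "severity": io.write_severity(severity, out / "severity_inputs.csv"),
        "truth": io.write_truth(syn, truth, out / "truth.json"),
    }
    _stage_log("simulate", f"wrote {len(paths)} input tables to {out}")
    return paths


def stage_fit(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    indicators = io.read_indicators(cfg.require("indicators_path", "indicators.csv"))
    studies = io.read_studies(cfg.require("studies_path", "studies.csv"))
    paths = {}
    for dis in cfg.disorders:
        frame = metareg.build_model_frame(
            studies[studies["disorder"] == dis], indicators)
        _stage_log("fit", f"{dis}: step one on {len(frame)} observations")
        step1 = metareg.fit_indicator_model(
            frame, disorder=dis, excess_direction=cfg.excess_direction,
            trim=cfg.trim, n_draws=cfg.draws, seed=cfg.seed)
        used_threshold = cfg.p_threshold
        idx = metareg.compute_impact_index(
            frame[list(metareg.INDICATOR_NAMES)], step1,
            p_threshold=used_threshold, per_draw=False)
        if np.ptp(np.asarray(idx)) == 0.0:
            # no indicator reached significance: keep the chain defined by
            # building the index from all indicator coefficients
            _stage_log("fit", f"{dis}: no indicator significant at "
                       f"p<{cfg.p_threshold}; index built from all indicators")
            used_threshold = 1.0
            idx = metareg.compute_impact_index(
                frame[list(metareg.INDICATOR_NAMES)], step1,
                p_threshold=used_threshold, per_draw=False)
        step2 = metareg.fit_final_model(
            frame, idx, candidates=validate_mod.step2_candidates(frame),
            disorder=dis, n_draws=cfg.draws, seed=cfg.seed + 1)
        _stage_log("fit", f"{dis}: final model kept "
                   f"{[n for n in step2.names if n != 'index']} "
                   f"(dropped {[e['dropped'] for e in step2.elimination_log]})")
        summ = pd.concat([step1.summary().assign(model="indicator"),
                          step2.summary().assign(model="final")])
        paths[f"coefficients_{dis}"] = io.write_csv(
            summ, out / f"coefficients_{dis}.csv")
        draw_frames = []
        for fit, model in ((step1, "indicator"), (step2, "final")):
            d = pd.DataFrame(fit.draws.T, columns=[f"draw_{i}" for i in
                                                   range(fit.draws.shape[0])])
            d.insert(0, "covariate", fit.names)
            d.insert(0, "model", model)
            d.insert(2, "re_var_intercept", fit.re_var_intercept)
            d.insert(3, "re_var_indicator", fit.re_var_indicator)
            d.insert(4, "index_p_threshold", used_threshold)
            draw_frames.append(d)
        paths[f"draws_{dis}"] = io.write_csv(
            pd.concat(draw_frames, ignore_index=True),
            out / f"draws_{dis}.csv")
    return paths


def _load_fits(cfg: PipelineConfig, dis: str):
    """Rebuild CoefficientSet pairs (and the index p-threshold the fit
    stage actually used) from the draw files, for standalone stages."""
    df = pd.read_csv(Path(cfg.out_dir) / f"draws_{dis}.csv")
    used_threshold = float(df["index_p_threshold"].iloc[0])
    dcols = [c for c in df.columns if c.startswith("draw_")]
    fits = {}
    for model, g in df.groupby("model"):
        draws = g[dcols].to_numpy(float).T
        names = list(g["covariate"])
        roles = {}
        for n in names:
            if n in metareg.INDICATOR_NAMES:
                roles[n] = "indicator"
            elif n == "index":
                roles[n] = "index"
            elif n in metareg.ADDITIVE_NAMES:
                roles[n] = "additive_bias"
            else:
                roles[n] = "modifier"
        mean, sd = draws.mean(axis=0), draws.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, np.abs(mean) / sd,
                         np.where(mean == 0, 0.0, np.inf))
        from scipy import stats
        fits[model] = metareg.CoefficientSet(
            disorder=dis, names=names, beta=mean,
            cov=np.cov(draws.T) if draws.shape[1] > 1 else np.atleast_2d(np.var(draws)),
            draws=draws,
            re_var_intercept=float(g["re_var_intercept"].iloc[0]),
            re_var_indicator=float(g["re_var_indicator"].iloc[0]),
            roles=roles, pvalues=2.0 * stats.norm.sf(z),
            loglik=np.nan, aic=np.nan, n_obs=0)
    return fits["indicator"], fits["final"], used_threshold


def stage_adjust(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    indicators = io.read_indicators(cfg.require("indicators_path", "indicators.csv"))
    surfaces = io.read_baseline(cfg.require("baseline_path", "baseline_prevalence.csv"))
    populations = io.read_populations(cfg.require("populations_path", "populations.csv"))
    adjusted_all, change_all = [], []
    for dis in cfg.disorders:
        step1, step2, used_threshold = _load_fits(cfg, dis)
        sub = surfaces[surfaces["disorder"] == dis].reset_index(drop=True)
        _stage_log("adjust", f"{dis}: adjusting {len(sub)} surface cells x "
                   f"{cfg.draws} draws over the daily series")
        adj = adjust_mod.adjust_surfaces(sub, indicators, step1, step2,
                                         p_threshold=used_threshold)
        _, agg = adjust_mod.change_accounting(adj, populations)
        adjusted_all.append(adj)
        change_all.append(agg)
    adjusted = pd.concat(adjusted_all, ignore_index=True)
    change = pd.concat(change_all, ignore_index=True)
    return {"adjusted": io.write_csv(adjusted, out / "adjusted_prevalence.csv"),
            "change": io.write_csv(change, out / "change_table.csv")}


def stage_burden(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    adjusted = pd.read_csv(Path(cfg.out_dir) / "adjusted_prevalence.csv")
    populations = io.read_populations(cfg.require("populations_path", "populations.csv"))
    severity = io.read_severity(cfg.require("severity_path", "severity_inputs.csv"))
    _stage_log("burden", f"computing YLD/DALY tables "
               f"(comorbidity scalar {cfg.comorbidity_scalar})")
    table = burden_mod.burden_table(adjusted, severity, populations,
                                    comorbidity_scalar=cfg.comorbidity_scalar)
    return {"burden": io.write_csv(table, out / "burden_table.csv")}


def stage_validate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    indicators = io.read_indicators(cfg.require("indicators_path", "indicators.csv"))
    studies = io.read_studies(cfg.require("studies_path", "studies.csv"))
    rows = []
    for dis in cfg.disorders:
        results = validate_mod.loco_cv(studies, indicators, dis,
                                       n_draws=cfg.draws, seed=cfg.seed)
        for r in results:
            for p in r.predictions.itertuples(index=False):
                rows.append({"disorder": dis,
                             "held_out_location": r.held_out_location,
                             "n_train": r.n_train,
                             "flagged": ";".join(r.flagged_covariates),
                             **p._asdict()})
        cov = float(np.mean([r.coverage_rate for r in results]))
        _stage_log("validate", f"{dis}: LOCO mean coverage {cov:.3f} over "
                   f"{len(results)} held-out countries")
    return {"loco": io.write_csv(pd.DataFrame(rows), out / "loco_report.csv")}


def run_pipeline(cfg: PipelineConfig, simulate: bool = True) -> Path:
    """Execute all stages and write a run manifest. Returns the output dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {}
    if simulate:
        inputs = {k: str(v) for k, v in stage_simulate(cfg).items()}
    else:
        for name, default in (("indicators_path", "indicators.csv"),
                              ("studies_path", "studies.csv"),
                              ("baseline_path", "baseline_prevalence.csv"),
                              ("populations_path", "populations.csv"),
                              ("severity_path", "severity_inputs.csv")):
            inputs[name] = str(cfg.require(name, default))
    outputs = {}
    for stage_name, fn in (("fit", stage_fit), ("adjust", stage_adjust),
                           ("burden", stage_burden), ("validate", stage_validate)):
        try:
            outputs.update({k: str(v) for k, v in fn(cfg).items()})
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage_name!r} failed: {err}") from err
    io.write_manifest(out / "manifest.json", seed=cfg.seed, inputs=inputs,
                      outputs=outputs,
                      extra={"draws": cfg.draws,
                             "disorders": list(cfg.disorders),
                             "comorbidity_scalar": cfg.comorbidity_scalar})
    _stage_log("run", f"pipeline complete; manifest at {out / 'manifest.json'}")
    return out
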