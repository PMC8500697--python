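"""CSV dialects, ground-truth sidecars and run manifests.

All tables are UTF-8 CSV with ISO-8601 dates; column layouts are documented
in docs/formats.md. The truth sidecar (JSON) records the generative config
and per-study ground truth so every synthetic run is auditable; the manifest
records seeds, the package version and SHA-256 hashes of every input so each
output table is re-derivable from inputs plus manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from .burden import SEVERITIES, SeverityInputs

__all__ = ["write_csv", "read_indicators", "read_studies", "read_baseline",
           "read_populations", "write_severity", "read_severity",
           "write_truth", "read_truth", "write_manifest", "sha256_of"]


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _require(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_indicators(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["location_id", "date", "mobility_decrease", "infection_rate",
                  "excess_mortality_rate"], path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_studies(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["sample_id", "location_id", "disorder", "prev_pre",
                  "prev_mid", "n_pre", "n_mid", "mean_age", "prop_female",
                  "design", "combined_symptoms", "mid_start", "mid_end"], path)
    return df


def read_baseline(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["disorder", "location_id", "age_lo", "age_hi", "sex",
                  "draw_0"], path)
    return df


def read_populations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["location_id", "age_lo", "age_hi", "sex", "population"], path)
    return df


def write_severity(severity_by_disorder: dict, path) -> Path:
    rows = []
    for dis, sev in severity_by_disorder.items():
        for s in SEVERITIES:
            rows.append({"disorder": dis, "severity": s,
                         "proportion": sev.proportions[s],
                         "weight": sev.weights[s]})
    return write_csv(pd.DataFrame(rows), path)


def read_severity(path) -> dict:
    df = pd.read_csv(path)
    _require(df, ["disorder", "severity", "proportion", "weight"], path)
    out = {}
    for dis, g in df.groupby("disorder"):
        g = g.set_index("severity")
        out[dis] = SeverityInputs(
            disorder=dis,
            proportions={s: float(g.loc[s, "proportion"]) for s in SEVERITIES},
            weights={s: float(g.loc[s, "weight"]) for s in SEVERITIES},
        ).validate()
    return out


def write_truth(config, truth_df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config": dataclasses.asdict(config),
               "studies": truth_df.to_dict(orient="records")}
    path.write_text(json.dumps(payload, indent=1, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_truth(path) -> tuple[dict, pd.DataFrame]:
    payload = json.loads(Path(path).read_text())
    return payload["config"], pd.DataFrame(payload["studies"])


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, seed, inputs: dict, outputs: dict,
                   extra: dict | None = None) -> Path:
    from . import __version__
    path = Path(path)
    manifest = {
        "package": "mhshock",
        "version": __version__,
        "seed": int(seed),
        "input_hashes": {k: sha256_of(v) for k, v in inputs.items()},
        "output_hashes": {k: sha256_of(v) for k, v in outputs.items()},
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
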