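"""Reading and writing the pipeline's CSV/TSV/JSON artifacts.

All files are UTF-8 CSV with dot decimals and a mandatory header; timepoints
are integer minutes and amounts are ng per 400 mL breath sample.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from . import simulate as sim

WASHOUT_COLUMNS = ["subject_id", "group", "timepoint_min", "limonene_ng", "censored"]

_DIST_TYPES = {"lognormal": sim.LogNormal, "beta": sim.Beta, "fixed": sim.Fixed}


def read_washout_csv(path) -> pd.DataFrame:
    """Load and validate a long-format washout table.

    Requires the canonical five columns (extras are preserved but ignored),
    strictly positive amounts, and no duplicate (subject, timepoint) pairs.
    Rows come back sorted by (subject_id, timepoint_min).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # noqa: BLE001 - surface as schema error
        raise ParseError(f"{path}: cannot read CSV ({e})") from e
    missing = [c for c in WASHOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    tp = pd.to_numeric(df["timepoint_min"], errors="coerce")
    amt = pd.to_numeric(df["limonene_ng"], errors="coerce")
    for name, col in (("timepoint_min", tp), ("limonene_ng", amt)):
        bad = col.isna() & df[name].notna() | col.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(f"{path}: non-numeric {name} at data row {row}")
    if (amt <= 0).any():
        row = int(np.flatnonzero((amt <= 0).to_numpy())[0])
        raise ParseError(f"{path}: non-positive amount at data row {row}")
    df["timepoint_min"] = tp.astype(int)
    df["limonene_ng"] = amt.astype(float)
    df["censored"] = df["censored"].astype(bool)
    dup = df.duplicated(subset=["subject_id", "timepoint_min"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError(f"{path}: duplicate (subject, timepoint) at data row {row}")
    return df.sort_values(["subject_id", "timepoint_min"]).reset_index(drop=True)


def write_washout_csv(df: pd.DataFrame, path) -> None:
    out = df.sort_values(["subject_id", "timepoint_min"]).reset_index(drop=True)
    out.to_csv(path, index=False)


def read_subjects_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ParseError(f"{path}: subjects table needs subject_id and group")
    for col in ("portal_htn", "thrombocytopenia", "splenomegaly"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def read_kinetics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"subject_id", "group", "cmax_ng", "auc_0_90"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: kinetics table missing {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _dist_from_dict(d) -> object:
    if isinstance(d, (int, float)):
        return sim.Fixed(float(d))
    kind = str(d.get("kind", "lognormal")).lower()
    cls = _DIST_TYPES.get(kind)
    if cls is None:
        raise ParseError(f"unknown distribution kind '{kind}'")
    kwargs = {k: v for k, v in d.items() if k != "kind"}
    return cls(**kwargs)


def _dist_to_dict(dist) -> object:
    if isinstance(dist, sim.Fixed):
        return {"kind": "fixed", "value": dist.value}
    if isinstance(dist, sim.LogNormal):
        return {"kind": "lognormal", "median": dist.median, "sigma_log": dist.sigma_log}
    if isinstance(dist, sim.Beta):
        return {"kind": "beta", "a": dist.a, "b": dist.b, "scale": dist.scale}
    raise ParseError(f"cannot serialize distribution {dist!r}")


def load_config(path) -> sim.SimConfig:
    """Build a SimConfig from a YAML file; absent keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in ("ka_per_min", "ke_per_min"):
            kwargs[key] = _dist_from_dict(val)
        elif key in ("cl_int_rel", "shunt_fraction", "baseline_ng"):
            kwargs[key] = {g: _dist_from_dict(v) for g, v in val.items()}
        elif key == "score_coupling":
            kwargs[key] = {k: sim.ScoreCoupling(**v) for k, v in val.items()}
        elif key == "timepoints_min":
            kwargs[key] = tuple(int(t) for t in val)
        else:
            kwargs[key] = val
    return sim.SimConfig(**kwargs)


def config_to_dict(cfg: sim.SimConfig) -> dict:
    """JSON/YAML-serializable snapshot of a SimConfig."""
    from dataclasses import asdict

    return {
        "n_control": cfg.n_control, "n_cirrhosis": cfg.n_cirrhosis,
        "dose_ng": cfg.dose_ng, "timepoints_min": list(cfg.timepoints_min),
        "ka_per_min": _dist_to_dict(cfg.ka_per_min),
        "ke_per_min": _dist_to_dict(cfg.ke_per_min),
        "f_abs": cfg.f_abs,
        "cl_int_rel": {g: _dist_to_dict(v) for g, v in cfg.cl_int_rel.items()},
        "shunt_fraction": {g: _dist_to_dict(v) for g, v in cfg.shunt_fraction.items()},
        "breath_scale": cfg.breath_scale,
        "baseline_ng": {g: _dist_to_dict(v) for g, v in cfg.baseline_ng.items()},
        "loq_ng": cfg.loq_ng, "noise_cv": cfg.noise_cv,
        "score_coupling": {k: asdict(v) for k, v in cfg.score_coupling.items()},
        "missing_rate": cfg.missing_rate,
        "portal_htn_shunt_threshold": cfg.portal_htn_shunt_threshold,
        "seed": cfg.seed,
    }


def write_json(obj: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
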