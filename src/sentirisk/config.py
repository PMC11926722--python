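"""Run configuration: one structured file drives the whole pipeline.

The resolved configuration (defaults deep-merged with the user file) is
written next to every run's outputs, and together with the seed fully
determines all artifacts.
"""

from __future__ import annotations

import copy
import datetime as dt
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "config_hash"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "week_origin": "2019-01-01",
    "n_weeks": 187,
    "simulate": {
        "enabled": True,
        "graph": {"kind": "germany"},  # or {"kind": "lattice", rows, cols}
        "mean_ttw": 6000,
        "event": {
            "weeks": [129, 130, 131, 132],
            "regions": ["NW", "RP", "SL", "HE"],
            "precip_boost": 0.035,
        },
        "params": {
            "intercept": None,  # None -> log(0.1)
            "f_temp": [0.0, -0.005, 0.0, 0.020],
            "f_precip": [-0.0025, 0.0, 0.011],
            "field_tau": 2500.0,
            "ar_rho": 0.7,
            "event_effect_rr": 1.10,
        },
    },
    "inputs": {
        "panel": None,
        "climate": None,
        "graph": None,
        "docs": None,
        "lexicon": None,
    },
    "schemes": {
        "temperature": {
            "breaks": [15.0, 19.0, 23.0],
            "labels": ["low", "mid", "average", "high"],
        },
        "precipitation": {
            "breaks": [0.01, 0.035],
            "labels": ["low", "mid", "high"],
        },
    },
    "windows": {
        "before": ["2021-05-25", "2021-06-21"],
        "during": ["2021-06-22", "2021-07-19"],
        "after": ["2021-07-20", "2021-08-16"],
    },
    "model": {
        "field_structure": "icar_ar1",
        "effect_prior": "independent",
        "effect_rho": 0.8,
        "interaction": False,
        "tau_field": 200.0,
        "rho": 0.7,
        "tau_temp": 1.0,
        "tau_precip": 1.0,
        "tau_interaction": 1.0,
        "empirical_bayes": False,
        "intercept_precision": 1e-6,
        "max_iter": 50,
        "tol": 1e-9,
        "theta_tot": None,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None) -> dict:
    """User YAML merged over the defaults; None gives pure defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(DEFAULT_CONFIG, user)


def resolve_config(config: dict, out_dir: Path) -> Path:
    """Write the resolved config next to the run outputs."""
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))
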