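"""Pipeline configuration: defaults, YAML loading, dotted access, hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "filter": {"low_hz": 1.0, "high_hz": 48.0},
    "epoch": {"tmin_s": -1.0, "tmax_s": 1.5},
    "baseline": {"tmin_s": -0.5, "tmax_s": 0.0},
    "reject": {"threshold_uv": 100.0},
    "tfr": {
        "freq_min": 4.0,
        "freq_max": 30.0,
        "cycles_base": 3.0,
        "cycles_expansion": 0.5,
        "padratio": 2,
        "window_ms": 350.0,
        "power_window_s": [0.1, 0.7],
        "integer_padratio": 8,
        "integer_freqs": [4.0, 5.0, 6.0, 7.0, 8.0],
        "scale": "dB-vs-baseline",  # or "absolute"
    },
    "bank": {
        "bands": [
            {"name": "theta", "low": 4.0, "high": 8.0},
            {"name": "alpha", "low": 8.0, "high": 13.0},
            {"name": "beta", "low": 13.0, "high": 30.0},
        ],
        "include_gamma": False,
    },
    # average referencing leaves the covariance rank-deficient by one; a tiny
    # ridge on the trace-normalised covariances restores definiteness
    "csp": {"m": 2, "ridge": 1.0e-6, "window_s": [0.0, 1.5]},
    "mi": {"bins": None, "strategy": "quantile", "granularity": "trial", "top_k": 2},
    "behavior": {"backs": [3, 4], "group_block": 1, "k_sd": 2.0, "tie": "low"},
    "gcnn": {
        "layers": 2,
        "lr": 0.05,
        "epochs": 200,
        "seed": 0,
        "leaky_slope": 0.2,
        "norm_rule": "max",
        "attention_mode": "projection",
        "n_hidden": 4,
        "val_fraction": 0.25,
        "adjacency_update_rate": 0.3,
    },
    "recommend": {
        "candidate_channels": ["Fp1", "Fp2", "F3", "F4"],
        "channel_weight_threshold": 0.8,
    },
    "labels": {"source": "behavior"},  # or "simulation"
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = deep_update(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML override file."""
    cfg = default_config()
    if path is not None:
        override = yaml.safe_load(Path(path).read_text()) or {}
        cfg = deep_update(cfg, override)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration tree."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
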