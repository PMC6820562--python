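"""Run configuration: defaults plus YAML overrides.

Defaults mirror the task's analysis conventions: 100-ms SDF kernel on a
10-ms grid, 8.92 Hz / 254 us classification thresholds, 0.5 Hz inclusion
threshold, eight 0.5-s working-memory bins, 15+15 pseudo-trials, 100
decoding repeats with 90-unit ensembles (130 for the pre-stimulus
control).
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_sequential": 20,
        "n_persistent": 5,
        "n_untuned": 5,
        "n_interneurons": 5,
        "n_trials_per_condition": 83,
        "p_correct": 0.85,
    },
    "sdf": {
        "sigma_s": 0.1,
        "dt_s": 0.01,
    },
    "classification": {
        "rate_threshold_hz": 0.5,
    },
    "wm_bins": {
        "n_bins": 8,
        "bin_s": 0.5,
    },
    "sequentiality": {
        "ridge_halfwidth_s": 0.25,
        "n_entropy_bins": 8,
    },
    "decoding": {
        "enabled": True,
        "mode": "full_4s_ensemble_curve",
        "n_repeats": 100,
        "ensemble_size": 90,
        "prestim": False,
        "prestim_ensemble_size": 130,
        "n_per_class": 15,
    },
}


def merge_config(base: Dict[str, Any], override: Optional[Dict[str, Any]]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> Dict[str, Any]:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(Path(path)) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(DEFAULTS, user)
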