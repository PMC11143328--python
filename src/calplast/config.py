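"""Default analysis parameters and config-file loading.

All thresholds used across the pipeline live here so that a single config
file drives every CLI stage.  Values are the protocol defaults: detection
threshold and prominence 0.09 ΔF/F, 200 ms response window, shuffled-window
range −4.5 to −0.5 s, hotspot level 0.9 and off-hotspot band 0.3–0.67 on the
normalized scale, dependence rule R > 0.5, calcium-event inclusion criterion
0.9 ΔF/F with weak-responder factor 2.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "detect": {"threshold": 0.09, "prominence": 0.09, "inclusion_criterion": 0.9},
    "window": 0.2,
    "shuffle_range": [-4.5, -0.5],
    "smooth_window": 5,
    "f0_percentile": 20.0,
    "hotspot_level": 0.9,
    "off_band": [0.3, 0.67],
    "dependence_r": 0.5,
    "dependence_p": 0.05,
    "weak_factor": 2.0,
    "coverage_cutoff": 0.9,
    "delta_orientation": "post_minus_pre",
    "simulate": {
        "n_cells": 3,
        "regime": "both",
        "n_trials": 12,
        "frame_rate": 31.0,
        "trial_len": 10.0,
        "stim_time": 5.0,
        "noise_sd": 0.03,
        "linescan": {
            "n_pixels": 40,
            "pixel_len": 15.0,
            "hotspot_center": 20,
            "hotspot_width": 2.5,
            "noise_sd": 0.02,
        },
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a JSON or YAML config file."""
    if path is None:
        return json.loads(json.dumps(DEFAULTS))  # deep copy
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        override = yaml.safe_load(text) or {}
    else:
        override = json.loads(text)
    return _deep_merge(DEFAULTS, override)
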