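"""Run configuration: a single YAML file with per-stage sections.

Unknown keys are rejected so typos cannot silently fall back to defaults,
and a seed is mandatory so every run is reproducible.  The effective config
(defaults filled in) is hashed and written into the run manifest, making each
run self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from woundtrack.errors import ConfigError

#: allowed keys per section; None-valued defaults mean "stage decides"
SCHEMA: dict[str, dict] = {
    "seed": None,  # top-level scalar, mandatory
    "pixel_size": 0.5,
    "outdir": "runs",
    "scene": {
        "image_shape": [640, 640],
        "decay_length": 200.0,
        "n_cells": 40,
        "max_distance": 300.0,
        "cell_radius": 5.0,
        "membrane_thickness": 0.75,
        "vesicle_count": 12,
        "vesicle_sigma": 0.3,
        "cytosol_fraction": 0.25,
        "total_flux": 500000.0,
        "background_level": 100.0,
        "noise": ["poisson", 1.0],
    },
    "walkers": {
        "n_tracks": 50,
        "n_frames": 240,
        "dt": 30.0,
        "mean_speed": 8.0,
        "speed_sd": 2.0,
        "persistence": 0.5,
        "bias_strength": 3.0,
        "bias_range": 200.0,
        "dwell_frames": 10,
        "p_reverse": 0.3,
        "speed_cosine_coupling": 0.0,
        "fin_polygon": [[0, 0], [400, 0], [400, 300], [0, 300]],
        "owa_polygon": [[40, 120], [100, 120], [100, 180], [40, 180]],
    },
    "segmentation": {
        "images": None,
        "seeds": None,
        "threshold": None,
        "min_area_px": 50,
        "core_halfwidth": 5,
        "max_iterations": 200,
        "contour_thickness": 1,
    },
    "internalization": {
        "n_levels": 8,
        "offset": [0, 1],
        "symmetric": False,
        "zero_fill": False,
        "normalization": "movie_max",
        "bin_width_um": 25.0,
        "max_saturated_frac": 0.01,
        "min_distinct_levels": 4,
    },
    "trajectories": {
        "tracks": None,
        "owa": None,
        "fin": None,
        "min_duration": 3,
        "distance_bin_um": 25.0,
        "cosine_bins": 8,
        "cosine_zone_um": 50.0,
        "straightness_zone_um": 50.0,
        "straightness_min_path_um": 10.0,
        "aggregation": "per_step",
        "time_window_s": None,
    },
    "clusters": {
        "min_area_um2": 60.0,
        "recruitment_half_width_um": 100.0,
        "wound_center": None,
        "window": None,
    },
}


def _merge(defaults: dict, user: dict, path: str) -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path}{key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(source) -> dict:
    """Load and validate a run config from a YAML path, text, or dict."""
    if isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping")
    bad = [k for k in user if k not in SCHEMA]
    if bad:
        raise ConfigError(f"unknown config keys: {bad}")
    cfg = {}
    for key, default in SCHEMA.items():
        value = user.get(key, default)
        if isinstance(default, dict):
            value = _merge(default, user.get(key, {}) or {}, f"{key}.")
        cfg[key] = value
    if cfg.get("seed") is None:
        raise ConfigError("config must set an integer 'seed'")
    cfg["seed"] = int(cfg["seed"])
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of the effective configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
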