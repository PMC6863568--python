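"""Run configuration: schema, defaults, validation and JSON/YAML I/O.

A run config is a nested mapping with the sections below; ``load_config``
fills defaults, rejects unknown keys (naming the offending key path) and
returns a :class:`RunConfig`.  Configs round-trip: ``dump`` of a loaded
config loads back semantically identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "config_hash", "DEFAULTS"]

SCHEMA_VERSION = "1"

DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "out_dir": "polirkit_run",
    "deck": {"width_mm": 420.0, "depth_mm": 300.0, "z_travel_mm": 130.0},
    "optics": {
        "sensor_px": [3280, 2464],
        "fov_mm": [96.5, 72.5],
        "working_distance_mm": 80.0,
        "focus_z_mm": 80.0,
        "dof_mm": 10.0,
        "sigma_min_px": 1.28,
        "blur_slope_px_per_mm": 0.3,
        "noise": {"read_sigma": 0.0, "shot_gain": 0.0},
        "channels": "rgb",
    },
    "jitter": {"policy": "once", "mad_x_um": None, "mad_y_um": None},
    "scan": {
        "overlap_frac": 0.1,
        "interval_min": 10.0,
        "duration_h": 4.0,
        "homing": "once",
        "feedrate_mm_min": 3000.0,
        "z_mm": 80.0,
        "dwell_s": 0.5,
    },
    "scenario": {
        "pack": "ecoli_25922",
        "mode": "fluorescence",
        "milk_fraction": 0.0,
        "pathlength_mm": 0.206,
        "capillary_length_mm": 5.0,
        "strip_origin_mm": [2.0, 1.8],
        "control_fails": False,
    },
    "analysis": {
        "baseline_frames": 3,
        "k_sd": 5.0,
        "abs_floor_frac": 0.05,
        "rel_increase": 0.38,
        "min_range_frac": 0.05,
    },
    "qc": {"z_sweep_mm": 10.0, "z_step_mm": 2.0, "n_positional": 2000},
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    data: dict

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])


def _merge(defaults, given, path=""):
    if not isinstance(given, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        kp = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {kp}")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value, kp)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(source) -> RunConfig:
    """Load and validate a config from a JSON/YAML path or a mapping."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    else:
        raw = source
    data = _merge(DEFAULTS, raw or {})
    if str(data["schema_version"]) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {data['schema_version']!r}")
    if data["seed"] is None:
        raise ConfigError("seed is mandatory")
    return RunConfig(data=data)


def dump_config(config: RunConfig, path=None) -> str:
    text = yaml.safe_dump(config.data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.data, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
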