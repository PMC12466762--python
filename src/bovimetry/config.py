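"""YAML configuration with the pipeline's built-in defaults.

Precedence is CLI flag > config file > built-in default.  The defaults embed
the constants the pipeline is calibrated for: the 525/525/319.5/239.5 pinhole
intrinsics, the 0.1-5.0 m pass-through window, millimeter 16-bit PNG depth
encoding, five completion passes, the hoof-neighborhood ground-plane recipe,
and a uniform 0.05 OKS sigma per landmark.
"""

from __future__ import annotations

import copy

import yaml

from .frames import CameraIntrinsics, Extrinsics

__all__ = ["DEFAULTS", "load_config", "intrinsics_from_config", "extrinsics_from_config"]

DEFAULTS: dict = {
    "intrinsics": {"fx": 525.0, "fy": 525.0, "cx": 319.5, "cy": 239.5},
    "extrinsics": {"R": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
                   "T": [0.0, 0.0, 0.0]},
    "depth_scale": 0.001,
    "passthrough": {"z1": 0.1, "z2": 5.0},
    "completion": {"max_passes": 5},
    "ground": {"radius": 0.15, "min_support": 50, "stride": 1},
    "depth_lookup": "median",
    "oks": {"sigmas": [0.05] * 6,
            "thresholds": [round(0.50 + 0.05 * i, 2) for i in range(10)],
            "area_convention": "sqrt_area"},
    "landmark_aliases": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Built-in defaults, overlaid by a YAML file, overlaid by explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def intrinsics_from_config(cfg: dict) -> CameraIntrinsics:
    i = cfg["intrinsics"]
    return CameraIntrinsics(fx=i["fx"], fy=i["fy"], cx=i["cx"], cy=i["cy"])


def extrinsics_from_config(cfg: dict) -> Extrinsics:
    e = cfg["extrinsics"]
    return Extrinsics(e["R"], e["T"])
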