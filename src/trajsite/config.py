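"""Pipeline configuration: one YAML file drives every stage.

Thresholds are centralized here because they are the knobs every stage
shares; CLI flags may override the output directory and seed.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import RegionSpec

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "region_spec_from_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "output_dir": "trajsite_out",
    "seed": 1,
    "thresholds": {
        "contact_cutoff_nm": 0.4,
        "cis_threshold_nm": 0.32,
        "affinity_keep_max_kcal": -2.0,
        "affinity_favorable_max_kcal": -4.0,
        "affinity_unfavorable_min_kcal": 0.0,
        "hbond_distance_nm": 0.35,
        "hbond_angle_deg": 30.0,
    },
    "windows": {
        "equilibrium_fraction": 0.25,
    },
    "sampling": {
        "discard_ns": 0.0,
        "stride_ns": 1.0,
        "boundary": "inclusive",
    },
    "regions": {
        "default": "cytoplasmic",
        "ranges": [],
    },
    "ligand": {
        "residue_name": None,  # autodetect non-standard residues by default
    },
    "inputs": {},
    "synth": {},
    "clustering": {"k": 3, "seed": 1234, "restarts": 50},
}


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = copy.deepcopy(dict(base))
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None) -> dict[str, Any]:
    """DEFAULT_CONFIG overlaid with the YAML file (missing file -> error)."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    return merge_config(DEFAULT_CONFIG, user)


def region_spec_from_config(config: Mapping[str, Any]) -> RegionSpec:
    ranges = [(str(lbl), int(a), int(b)) for lbl, a, b in config["regions"]["ranges"]]
    return RegionSpec(ranges)
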