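"""Run configuration: YAML/JSON files mapped onto the package's settings.

Schema (all sections optional unless a command needs them)::

    roi_parenchyma: {row_start: 10, row_end: 110, col_start: 20, col_end: 120}
    roi_plexus:     {row_start: 10, row_end: 110, col_start: 140, col_end: 240}
    thresholds:     {t_intensive: 10, t_normal: 40}
    network:        {input_height: 100, input_width: 100, ...}
    training:       {learning_rate: 0.001, max_epochs: 200, ...}
    phantom:        {jitter_sd: 2.0, speckle_shape: 60, ...}

ROI coordinates are 0-based half-open by default; pass
``one_based_inclusive=True`` (CLI ``--one-based-inclusive``) for
MATLAB-style bounds.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .density import RegionSpec, ThresholdSet
from .network import NetworkConfig, TrainingConfig
from .phantom import PhantomConfig

__all__ = [
    "load_config",
    "region_from_dict",
    "thresholds_from_dict",
    "network_from_dict",
    "training_from_dict",
    "phantom_from_dict",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def region_from_dict(d: dict, one_based_inclusive: bool = False) -> RegionSpec:
    keys = ("row_start", "row_end", "col_start", "col_end")
    missing = [k for k in keys if k not in d]
    if missing:
        raise ValueError(f"ROI spec missing keys {missing}")
    vals = [int(d[k]) for k in keys]
    if one_based_inclusive:
        return RegionSpec.from_one_based_inclusive(*vals)
    return RegionSpec(*vals)


def thresholds_from_dict(d: dict | None) -> ThresholdSet:
    d = d or {}
    return ThresholdSet(
        t_intensive=float(d.get("t_intensive", 10.0)),
        t_normal=float(d.get("t_normal", 40.0)),
    )


def network_from_dict(d: dict | None) -> NetworkConfig:
    d = dict(d or {})
    if "block_channels" in d:
        d["block_channels"] = tuple(d["block_channels"])
    return NetworkConfig(**d)


def training_from_dict(d: dict | None) -> TrainingConfig:
    d = dict(d or {})
    if "fractions" in d:
        d["fractions"] = tuple(d["fractions"])
    return TrainingConfig(**d)


def phantom_from_dict(d: dict | None) -> PhantomConfig:
    d = dict(d or {})
    if "patch_size" in d:
        d["patch_size"] = tuple(d["patch_size"])
    if "delta_e_targets" in d:
        d["delta_e_targets"] = tuple(
            (str(k), float(v)) for k, v in dict(d["delta_e_targets"]).items()
        )
    if "thresholds" in d:
        d["thresholds"] = thresholds_from_dict(d["thresholds"])
    return PhantomConfig(**d)
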