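"""Run configuration: profiles, YAML loading, and run manifests.

Two built-in profiles:

* ``desk``  — 64x64 scenes, a narrow model (3 encoder stages, 6 base
  channels) and 12 epochs (3 frozen, learning rate 3e-4): small enough to
  train on one CPU core in under a minute per arm while preserving every
  mechanism of the full recipe.
* ``paper`` — the clinical-scale recipe: 224x224 inputs, 4 encoder stages,
  64 base channels, 50 epochs (10 frozen), learning rate 1e-4, ImageNet
  channel normalization.

A YAML config may override any field; unknown keys are rejected with their
full path before any computation starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Any

import yaml

from .model import ModelConfig
from .trainer import TrainConfig

PROFILES: dict[str, dict] = {
    "desk": {
        "lr": 3e-4,
        "sigma_lr": 1e-2,
        "weight_decay": 5e-4,
        "batch_size": 4,
        "freeze_epochs": 3,
        "total_epochs": 12,
        "augment": True,
        "normalize": "unit",
        "model": {
            "encoder_depth": 3,
            "base_channels": 6,
            "dropout_rate": 0.5,
            "cls_blocks": 2,
            "input_side": 64,
        },
    },
    "paper": {
        "lr": 1e-4,
        "sigma_lr": 1e-2,
        "weight_decay": 5e-4,
        "batch_size": 4,
        "freeze_epochs": 10,
        "total_epochs": 50,
        "augment": True,
        "normalize": "imagenet",
        "model": {
            "encoder_depth": 4,
            "base_channels": 64,
            "dropout_rate": 0.5,
            "cls_blocks": 2,
            "input_side": 224,
        },
    },
}


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set, path: str = "") -> None:
    for k in d:
        if k not in allowed:
            raise ConfigError(f"unknown config key {path + k!r}")


def build_train_config(profile: str = "desk", overrides: dict | None = None,
                       **kwargs) -> TrainConfig:
    """Merge profile defaults, an optional override dict (e.g. from YAML),
    and keyword arguments into a validated TrainConfig."""
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; "
                          f"choose from {sorted(PROFILES)}")
    merged: dict = json.loads(json.dumps(PROFILES[profile]))  # deep copy
    for src in (overrides or {}), kwargs:
        for k, v in src.items():
            if k == "model" and isinstance(v, dict):
                merged["model"].update(v)
            else:
                merged[k] = v
    train_fields = {f.name for f in dataclasses.fields(TrainConfig)}
    model_fields = {f.name for f in dataclasses.fields(ModelConfig)}
    _check_keys(merged, train_fields)
    _check_keys(merged.get("model", {}), model_fields, path="model.")
    model_cfg = ModelConfig(**merged.pop("model", {}))
    return TrainConfig(model=model_cfg, **merged)


def load_yaml_config(path: str) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    return doc


def config_as_dict(cfg: TrainConfig) -> dict:
    return dataclasses.asdict(cfg)


def write_run_manifest(outdir: str, cfg: TrainConfig, seed: int,
                       inputs: dict[str, str], extra: dict | None = None) -> str:
    """Record everything needed to reproduce a run: the full config
    snapshot, the content hash of each input file, and the root seed."""
    hashes = {}
    for name, p in inputs.items():
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            h.update(fh.read())
        hashes[name] = h.hexdigest()
    from . import __version__

    manifest = {
        "config": config_as_dict(cfg),
        "seed": seed,
        "input_hashes": hashes,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = os.path.join(outdir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
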