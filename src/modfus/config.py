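"""Run configuration: YAML loading, defaults, validation, seed fan-out.

The resolved config is a nested dict with the published defaults
(λ = 0.54, τ = 0.1, 8 heads, depth-1 CMA, 512-d shared space, N = 8 prompt
variants, K = 5 folds, AdamW lr 1e-5 / weight decay 1e-5).  Unknown keys are
rejected with the offending key path in the message.  A single global seed
fans out deterministically to per-stage seeds by hashing the stage name.
"""

from __future__ import annotations

import copy
import hashlib

import yaml

from .exceptions import ConfigError

__all__ = ["DEFAULT_CONFIG", "load_run_config", "resolve_config", "derive_seed"]

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "out_dir": ".",
    "log_level": "INFO",
    "scales": None,  # path to a scale-definition YAML; None = shipped defaults
    "model": {
        "shared_dim": 512,
        "d_model": 32,
        "image_stages": 2,
        "text_layers": 2,
        "encoder_heads": 4,
        "heads": 8,
        "cma_depth": 1,
        "cma_residual": True,
        "hidden": 256,
        "patch_size": 8,
        "max_len": 64,
        "image_freeze_mask": None,
        "text_freeze_mask": None,
    },
    "train": {
        "tau": 0.1,
        "lambda": 0.54,
        "lr": 1.0e-5,
        "weight_decay": 1.0e-5,
        "batch_size": 32,
        "epochs": 30,
        "pretrain_epochs": 20,
        "n_augment": 8,
        "reduction": "sum",
        "image_noise_sd": 0.2,
    },
    "cv": {
        "folds": 5,
        "global_pretrain": False,
    },
    "cohort": {
        "n": 100,
        "pd_fraction": 234 / 383,
        "volume_shape": [32, 32, 32],
        "score_effect": 1.0,
        "image_effect": 0.5,
        "lesion_radius": 5.0,
        "noise_sd": 0.1,
        "coupling": 0.5,
    },
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_run_config(path=None) -> dict:
    """Load a YAML config file merged over the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return _merge(DEFAULT_CONFIG, doc)


def resolve_config(path=None, **overrides) -> dict:
    """Config from file plus dotted-key overrides (e.g. ``train.lr=1e-3``)."""
    cfg = load_run_config(path)
    for dotted, value in overrides.items():
        if value is None:
            continue
        keys = dotted.split("__")
        node = cfg
        for k in keys[:-1]:
            if k not in node:
                raise ConfigError(f"unknown configuration key: {dotted}")
            node = node[k]
        if keys[-1] not in node:
            raise ConfigError(f"unknown configuration key: {dotted}")
        node[keys[-1]] = value
    return cfg


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{stage}:{int(global_seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
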