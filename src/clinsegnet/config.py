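"""Run configuration: one nested YAML document, strict about unknown keys.

The shipped defaults reproduce every published hyperparameter of the
framework: main training (Adam, lr 5e-4, batch 8, 50 epochs, 224 input,
32-dim organ embedding), the loss weights (Tversky alpha 0.3 / beta 0.7,
HistoLoss 0.3 BCE + 0.7 Tversky, total 1.0 Histo + 0.4 edge) and the
HITL stage (ratio 0.30, at least 2 per class, lr 2e-4, weight decay 1e-2,
batch 8, 8 epochs, one-cycle schedule).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "validate_config"]

DEFAULTS: dict = {
    "seed": 0,
    "synth": {
        "image_size": 512,
        "n_lesions": [2, 5],
        "lesion_radius": [20, 60],
        "dab_hue": [20.0, 40.0],
        "background_hue": 220.0,
        "stain_jitter": 0.05,
        "organs": ["kidney", "liver", "lung"],
        "per_organ": 4,
    },
    "weaklabel": {
        "hue_band": [15.0, 45.0],
        "blue_band": [180.0, 260.0],
        "sat_min": 0.15,
        "val_max": 1.0,
        "gaussian_sigma": 2.0,
        "dab_min": 0.05,
        "min_area": 64,
        "open_radius": 2,
        "close_radius": 2,
        "fill_holes": True,
        "patch": 512,
        "stride": 256,
    },
    "prep": {
        "train_fraction": 0.8,
        "augment": True,
    },
    "network": {
        "in_channels": 1,
        "stage_channels": [64, 128, 256, 512, 256, 128, 64],
        "embed_dim": 32,
        "se_reduction": 16,
        "use_se": True,
        "use_film": True,
        "use_edge": True,
        "input_size": 224,
    },
    "loss": {
        "alpha": 0.3,
        "beta": 0.7,
        "epsilon": 1e-6,
        "w_bce": 0.3,
        "w_tversky": 0.7,
        "w_histo": 1.0,
        "w_edge": 0.4,
    },
    "train": {
        "optimiser": "adam",
        "lr": 5.0e-4,
        "batch_size": 8,
        "max_epochs": 50,
        "selection_metric": "recall",
        "threshold": 0.5,
    },
    "hitl": {
        "hitl_ratio": 0.30,
        "min_per_class": 2,
        "lr": 2.0e-4,
        "weight_decay": 1.0e-2,
        "batch_size": 8,
        "epochs": 8,
        "scheduler": "one-cycle",
        "ema_decay": 0.999,
    },
    "eval": {
        "threshold": 0.5,
        "pixel_pooled": False,
    },
}


def validate_config(cfg: dict, defaults: dict = DEFAULTS, path: str = "") -> None:
    """Reject keys that do not exist in the default schema."""
    for key, value in cfg.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise KeyError(f"{here!r} must be a mapping")
            validate_config(value, defaults[key], here)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and a dotted-key
    override mapping (e.g. {"train.lr": 1e-3})."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        validate_config(user)
        cfg = _merge(cfg, user)
    for dotted, value in (overrides or {}).items():
        keys = dotted.split(".")
        probe = DEFAULTS
        for k in keys[:-1]:
            if not isinstance(probe, dict) or k not in probe:
                raise KeyError(f"unknown configuration key: {dotted!r}")
            probe = probe[k]
        if not isinstance(probe, dict) or keys[-1] not in probe:
            raise KeyError(f"unknown configuration key: {dotted!r}")
        node = cfg
        for k in keys[:-1]:
            node = node[k]
        node[keys[-1]] = value
    return cfg
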