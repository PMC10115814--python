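"""YAML configuration: defaults, loading, and model construction."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .models import build_model
from .swin_encoder import SwinConfig

DEFAULTS: dict = {
    "model": {
        "C": 96,
        "num_classes": 2,
        "unet": {"base_channels": None},      # None -> C // 2
        "swin": {
            "depths": [2, 2, 6, 2],
            "heads": [3, 6, 12, 24],
            "window": 7,
            "mlp_ratio": 4.0,
        },
        "dfa": {"channels": 48, "dilations": [1, 3, 5, 7]},
        "ff": {"residual_depth": 2},
        "att": {"per_channel_gate": False},
    },
    "train": {
        "epochs": 300,
        "batch_size": 16,
        "learning_rate": 1.0e-3,
        "weight_decay": 1.0e-4,
        "image_size": 224,
        "seed": 0,
        "loss_weights": [0.5, 0.2, 0.3],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = DEFAULTS
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def swin_config_from(cfg: dict) -> SwinConfig:
    m = cfg["model"]
    return SwinConfig(
        embed_dim=m["C"],
        depths=tuple(m["swin"]["depths"]),
        heads=tuple(m["swin"]["heads"]),
        window=m["swin"]["window"],
        mlp_ratio=m["swin"]["mlp_ratio"],
    )


def model_from_config(variant: str, cfg: dict, seed: int | None = None):
    m = cfg["model"]
    return build_model(
        variant,
        swin_config=swin_config_from(cfg),
        num_classes=m["num_classes"],
        per_channel_gate=m["att"]["per_channel_gate"],
        seed=seed,
    )
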