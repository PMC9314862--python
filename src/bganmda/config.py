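"""YAML configuration: one flat file covering similarity, network and training knobs."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .bgan_model import NetworkSpec, TrainConfig
from .similarity import SimilarityParams

__all__ = ["load_config", "split_config"]


def load_config(path=None) -> dict:
    """Read a flat YAML mapping of hyperparameters (empty dict if no path)."""
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return raw


def split_config(raw: dict) -> tuple[SimilarityParams, dict, TrainConfig]:
    """Partition a flat config dict into the three parameter groups.

    Returns (similarity params, network-spec kwargs, training config).  The
    network kwargs lack ``input_dim``, which only the data can supply.
    Unknown keys raise.
    """
    sim_keys = {f.name for f in fields(SimilarityParams)}
    net_keys = {f.name for f in fields(NetworkSpec)} - {"input_dim"}
    train_keys = {f.name for f in fields(TrainConfig)}
    sim, net, trn = {}, {}, {}
    for key, value in raw.items():
        if key in sim_keys:
            sim[key] = value
        elif key in net_keys:
            net[key] = tuple(value) if isinstance(value, list) else value
        elif key in train_keys:
            trn[key] = tuple(value) if key == "betas" else value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return SimilarityParams(**sim), net, TrainConfig(**trn)
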