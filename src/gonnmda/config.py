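"""Run configuration: YAML loading, validation, defaults, seed fan-out.

Defaults are the model's published operating point (SVD rank 150, four
ordered-GNN layers, chunk size 128, dropout 0.2, MLP hidden size 1024 with
2 layers, embedding dimension 1024); desk-scale runs override the widths
and the SVD rank is clamped to the input size at fit time.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict

import numpy as np
import yaml

from gonnmda.fusion import FUSION_MODES
from gonnmda.ordered_gnn import OrderedGNNConfig


@dataclass
class FusionConfig:
    k_svd: int = 150
    mode: str = "vk_sigma"

    def validate(self):
        if self.k_svd < 1:
            raise ValueError("fusion.k_svd must be >= 1")
        if self.mode not in FUSION_MODES:
            raise ValueError(f"fusion.mode must be one of {FUSION_MODES}")


@dataclass
class GNNConfig:
    layers: int = 4
    chunk_size: int = 128
    dropout: float = 0.2
    aggregator: str = "mean"

    def validate(self, embed_dim: int):
        if self.layers < 1:
            raise ValueError("gnn.layers must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("gnn.dropout must be in [0, 1)")
        if self.aggregator not in ("mean",):
            raise ValueError("gnn.aggregator must be 'mean'")
        if embed_dim % self.effective_chunk(embed_dim) != 0:
            raise ValueError(
                f"embed_dim {embed_dim} not divisible by chunk_size {self.chunk_size}"
            )

    def effective_chunk(self, embed_dim: int) -> int:
        # a chunk wider than the embedding degenerates to a single gate chunk
        return min(self.chunk_size, embed_dim)


@dataclass
class MLPSection:
    hidden: int = 1024
    layers: int = 2

    def validate(self):
        if self.hidden < 1 or self.layers < 1:
            raise ValueError("mlp.hidden and mlp.layers must be >= 1")


@dataclass
class TrainSection:
    lr: float = 1e-3
    epochs: int = 200
    patience: int = 20

    def validate(self):
        if self.lr <= 0 or self.epochs < 1 or self.patience < 0:
            raise ValueError("invalid training section")


@dataclass
class RunConfig:
    embed_dim: int = 1024
    seed: int = 0
    folds: int = 5
    fusion: FusionConfig = field(default_factory=FusionConfig)
    gnn: GNNConfig = field(default_factory=GNNConfig)
    mlp: MLPSection = field(default_factory=MLPSection)
    train: TrainSection = field(default_factory=TrainSection)
    paths: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        self.fusion.validate()
        self.gnn.validate(self.embed_dim)
        self.mlp.validate()
        self.train.validate()
        return self

    def gnn_config(self) -> OrderedGNNConfig:
        return OrderedGNNConfig(
            n_layers=self.gnn.layers,
            dim=self.embed_dim,
            chunk_size=self.gnn.effective_chunk(self.embed_dim),
            dropout=self.gnn.dropout,
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return int(h.generate_state(1)[0] % (2**31 - 1))

    def to_dict(self) -> Dict[str, Any]:
        return {
            "embed_dim": self.embed_dim,
            "seed": self.seed,
            "folds": self.folds,
            "fusion": {"k_svd": self.fusion.k_svd, "mode": self.fusion.mode},
            "gnn": {
                "layers": self.gnn.layers,
                "chunk_size": self.gnn.chunk_size,
                "dropout": self.gnn.dropout,
                "aggregator": self.gnn.aggregator,
            },
            "mlp": {"hidden": self.mlp.hidden, "layers": self.mlp.layers},
            "train": {
                "lr": self.train.lr,
                "epochs": self.train.epochs,
                "patience": self.train.patience,
            },
            "paths": dict(self.paths),
        }


def _apply(section, data: Dict[str, Any], prefix: str):
    known = {f.name for f in fields(section)}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown config key '{prefix}{key}'")
        setattr(section, key, value)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; absent keys fall back to defaults.

    Unknown keys are rejected with the offending key named.
    """
    cfg = RunConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        for key, value in raw.items():
            if key in ("fusion", "gnn", "mlp", "train"):
                _apply(getattr(cfg, key), value or {}, f"{key}.")
            elif key == "paths":
                cfg.paths = dict(value or {})
            elif key in ("embed_dim", "seed", "folds"):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
    return cfg.validate()
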