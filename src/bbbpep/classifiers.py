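"""Training and prediction wrappers around the numpy network engine."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from bbbpep import nn
from bbbpep.architectures import ArchitectureSpec, LayerSpec, build_architecture, instantiate
from bbbpep.features import FeatureTable


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the seed fully determines initialization,
    dropout masks and batch order."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainedModel:
    """An architecture spec, its fitted network, and the training history."""

    spec: ArchitectureSpec
    network: nn.Network
    config: TrainConfig

    @property
    def history(self) -> dict:
        return self.network.history

    def save(self, path: str) -> None:
        """Serialize spec + weights to an .npz checkpoint."""
        meta = {
            "name": self.spec.name,
            "input_dim": self.spec.input_dim,
            "input_kind": self.spec.input_kind,
            "layers": [
                {"kind": ls.kind, "label": ls.label, "dims": ls.dims} for ls in self.spec.layers
            ],
            "config": asdict(self.config),
            "history": self.network.history,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.network.params)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            spec = ArchitectureSpec(
                meta["name"],
                meta["input_dim"],
                meta["input_kind"],
                tuple(LayerSpec(l["kind"], l["label"], l["dims"]) for l in meta["layers"]),
            )
            network = instantiate(spec)
            for i, p in enumerate(network.params):
                p[...] = data[f"param_{i}"]
            network.history = meta["history"]
        model = cls(spec, network, TrainConfig(**meta["config"]))
        return model

    def write_training_log(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tloss\taccuracy\n")
            for i, (l, a) in enumerate(zip(self.history["loss"], self.history["accuracy"]), 1):
                fh.write(f"{i}\t{l:.6f}\t{a:.6f}\n")


def train(spec: ArchitectureSpec, table: FeatureTable, cfg: TrainConfig = TrainConfig()) -> TrainedModel:
    """Fit the architecture on a (scaled) labeled feature table."""
    if table.labels is None:
        raise ValueError("training requires a labeled feature table")
    if table.n_features != spec.input_dim:
        raise ValueError(
            f"table has {table.n_features} features but the architecture expects {spec.input_dim}"
        )
    network = instantiate(spec)
    network.fit(
        table.X,
        table.labels,
        lr=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        seed=cfg.seed,
    )
    return TrainedModel(spec, network, cfg)


def predict_proba(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Per-row class probabilities, columns (negative, positive); rows sum to 1."""
    if table.n_features != model.spec.input_dim:
        raise ValueError(
            f"table has {table.n_features} features but the model expects {model.spec.input_dim}"
        )
    return model.network.predict_proba(table.X)


def predict_labels(model: TrainedModel, table: FeatureTable, threshold: float = 0.5) -> np.ndarray:
    """Hard labels from the positive-class probability; ties go positive."""
    proba = predict_proba(model, table)
    return (proba[:, 1] >= threshold).astype(int)
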