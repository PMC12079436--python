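"""Per-peptide descriptor assembly and train-only min-max scaling.

Default layout (150 features):

    FV(20) | AAPIV(20) | RAAPIV(20) | PRIM-moments(30) | RPRIM-moments(30)
          | sequence-matrix-moments(30)

Each 30-block is the raw/central/Hahn moment compression of one 400-entry
incidence matrix or of the square sequence matrix. The layout is configurable
block-by-block, and the realized dimension is always derived from the data,
so classifier builders take the true input width as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from bbbpep.encoders import PrimStrategy, aapiv, frequency_vector, prim, raapiv, rprim
from bbbpep.moments import ORDER_PAIRS, matrix_moment_features, sequence_to_matrix
from bbbpep.sequences import CANONICAL_AA, LabeledDataset, Peptide

#: All block names in their fixed order.
ALL_BLOCKS = ("FV", "AAPIV", "RAAPIV", "PRIM", "RPRIM", "SEQMAT")

_MOMENT_NAMES = [
    f"{fam}_{a}{b}" for fam in ("raw", "central", "hahn") for a, b in ORDER_PAIRS
]


@dataclass(frozen=True)
class FeatureConfig:
    """Which descriptor blocks to compute and with what PRIM convention."""

    blocks: tuple = ALL_BLOCKS
    prim_strategy: PrimStrategy = PrimStrategy.FIRST_OCCURRENCE

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")

    @property
    def column_names(self) -> list:
        names: list = []
        for block in self.blocks:
            if block in ("FV", "AAPIV", "RAAPIV"):
                names.extend(f"{block}_{aa}" for aa in CANONICAL_AA)
            else:
                names.extend(f"{block}_{m}" for m in _MOMENT_NAMES)
        return names

    @property
    def n_features(self) -> int:
        return sum(20 if b in ("FV", "AAPIV", "RAAPIV") else 30 for b in self.blocks)


DEFAULT_CONFIG = FeatureConfig()


def featurize(p: Peptide, config: FeatureConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The descriptor vector of one peptide (length ``config.n_features``)."""
    parts = []
    for block in config.blocks:
        if block == "FV":
            parts.append(frequency_vector(p).astype(float))
        elif block == "AAPIV":
            parts.append(aapiv(p).astype(float))
        elif block == "RAAPIV":
            parts.append(raapiv(p).astype(float))
        elif block == "PRIM":
            parts.append(matrix_moment_features(prim(p, config.prim_strategy)))
        elif block == "RPRIM":
            parts.append(matrix_moment_features(rprim(p, config.prim_strategy)))
        elif block == "SEQMAT":
            parts.append(matrix_moment_features(sequence_to_matrix(p)))
    return np.concatenate(parts)


@dataclass
class FeatureTable:
    """A feature matrix with row ids and optional labels.

    ``scaling`` records the fitted min-max parameters ((data_min, data_max)
    per column) when the table has been scaled; ``None`` means raw values.
    """

    X: np.ndarray
    ids: list
    labels: Optional[np.ndarray] = None
    columns: list = field(default_factory=list)
    scaling: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not self.columns:
            self.columns = [f"f{i}" for i in range(self.X.shape[1])]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.X.shape[0]:
                raise ValueError("labels length must match the number of rows")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, indices) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            self.X[idx],
            [self.ids[i] for i in idx],
            None if self.labels is None else self.labels[idx],
            list(self.columns),
            self.scaling,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "id", self.ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        labels = df.pop("label").to_numpy() if "label" in df.columns else None
        ids = df.pop("id").astype(str).tolist()
        return cls(df.to_numpy(dtype=float), ids, labels, list(df.columns))


def featurize_dataset(
    dataset, config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureTable:
    """Featurize every peptide of a dataset, preserving order and labels."""
    peptides = list(dataset)
    if not peptides:
        raise ValueError("cannot featurize an empty dataset")
    X = np.stack([featurize(p, config) for p in peptides])
    labels = None
    if all(p.label is not None for p in peptides):
        labels = np.array([p.label for p in peptides], dtype=int)
    return FeatureTable(X, [p.id for p in peptides], labels, config.column_names)


def fit_apply_scaling(train: FeatureTable, *others: FeatureTable) -> tuple:
    """Min-max scale feature tables with parameters fitted on *train* only.

    Every training-column value maps into [0, 1]; a constant training column
    maps to 0 everywhere. Values in the other tables are transformed with the
    training parameters and are NOT clipped, so they may fall outside [0, 1].

    Returns ``(scaled_train, scaled_others..., scaler)``.
    """
    if len(train) == 0:
        raise ValueError("cannot fit scaling on an empty table")
    scaler = MinMaxScaler(clip=False)
    scaler.fit(train.X)

    def _apply(t: FeatureTable) -> FeatureTable:
        return FeatureTable(
            scaler.transform(t.X),
            list(t.ids),
            None if t.labels is None else t.labels.copy(),
            list(t.columns),
            scaling=(scaler.data_min_.copy(), scaler.data_max_.copy()),
        )

    return (_apply(train), *(_apply(t) for t in others), scaler)
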