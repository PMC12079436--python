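"""Synthetic labeled peptide sets and stratified train/test splitting.

The generator draws residues from a two-component multinomial: positives are
tilted toward a designated residue subset (by default the cationic/aromatic
set {K, R, L, F, W}, chosen because enrichment in basic and hydrophobic
residues is the hallmark composition signal of barrier-penetrating peptides),
negatives are tilted toward the complement. ``bias_strength`` interpolates
between a shared uniform composition (0) and fully disjoint compositions (1),
so it directly controls how learnable the classification problem is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bbbpep.sequences import CANONICAL_AA, LabeledDataset, Peptide

#: Residues over-represented in synthetic positives at bias_strength > 0.
DEFAULT_BIASED_RESIDUES = frozenset("KRLFW")


@dataclass(frozen=True)
class SplitSpec:
    """How to split a labeled dataset into train and test partitions.

    train_fraction is the per-class proportion assigned to training
    (floor rule: ``n_train = floor(train_fraction * class_size)``, remainder
    to test), matching a 77%/23% split of 425+425 as 327+327 / 98+98.
    """

    train_fraction: float = 0.77
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


def _class_probabilities(bias_strength: float, biased: frozenset) -> tuple:
    """Per-residue sampling probabilities for (positive, negative) classes."""
    in_subset = np.array([aa in biased for aa in CANONICAL_AA], dtype=float)
    n_in = in_subset.sum()
    n_out = 20 - n_in
    uniform = np.full(20, 1.0 / 20.0)
    p_pos = (1.0 - bias_strength) * uniform + bias_strength * in_subset / n_in
    p_neg = (1.0 - bias_strength) * uniform + bias_strength * (1.0 - in_subset) / n_out
    return p_pos, p_neg


def generate_synthetic_dataset(
    n_pos: int,
    n_neg: int,
    length_range: tuple = (5, 50),
    bias_strength: float = 0.5,
    seed: int = 0,
    biased_residues: frozenset = DEFAULT_BIASED_RESIDUES,
) -> LabeledDataset:
    """Generate a labeled peptide set with a class-dependent composition bias.

    Parameters
    ----------
    n_pos, n_neg : int
        Number of positive (label 1) and negative (label 0) peptides.
    length_range : (int, int)
        Inclusive bounds for sequence length, drawn uniformly; must lie in
        [5, 200] (typical peptide territory — anything longer is a protein).
    bias_strength : float in [0, 1]
        0 gives both classes the uniform residue composition (no signal);
        1 makes the class compositions disjoint.
    seed : int
        Fully determines the output.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    lo, hi = length_range
    if not (5 <= lo <= hi <= 200):
        raise ValueError(f"length_range must satisfy 5 <= lo <= hi <= 200, got {length_range}")
    if not (0.0 <= bias_strength <= 1.0):
        raise ValueError(f"bias_strength must be in [0, 1], got {bias_strength}")

    rng = np.random.default_rng(seed)
    p_pos, p_neg = _class_probabilities(bias_strength, biased_residues)
    alphabet = np.array(list(CANONICAL_AA))

    peptides = []
    for label, count, probs, prefix in ((1, n_pos, p_pos, "pos"), (0, n_neg, p_neg, "neg")):
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(alphabet[rng.choice(20, size=length, p=probs)])
            peptides.append(Peptide(f"{prefix}_{i + 1:04d}", seq, label))
    return LabeledDataset(peptides)


def stratified_split_indices(labels, spec: SplitSpec) -> tuple:
    """Deterministic per-class index split; returns (train_idx, test_idx).

    Each class contributes ``floor(train_fraction * class_size)`` samples to
    training; partitions are disjoint and jointly exhaustive. Indices are
    returned sorted so original dataset order is preserved within partitions.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train_idx: list = []
    test_idx: list = []
    if spec.stratified:
        classes = np.unique(labels)
        if any((labels == c).sum() == 0 for c in classes):
            raise ValueError("stratified split requires every class to be non-empty")
        for c in classes:
            members = np.flatnonzero(labels == c)
            perm = rng.permutation(members)
            n_train = int(np.floor(spec.train_fraction * len(members)))
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
    else:
        perm = rng.permutation(len(labels))
        n_train = int(np.floor(spec.train_fraction * len(labels)))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(test_idx, dtype=int))


def stratified_split(dataset: LabeledDataset, spec: SplitSpec) -> tuple:
    """Split a labeled dataset into (train, test) per :class:`SplitSpec`."""
    train_idx, test_idx = stratified_split_indices(dataset.labels, spec)
    return dataset.subset(train_idx), dataset.subset(test_idx)
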