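"""Composition- and position-specific peptide descriptors.

Five encoders, all indexed by the alphabetical residue order A..Y:

* ``frequency_vector`` (FV): 20 per-residue occurrence counts.
* ``aapiv``: accumulative absolute position incidence vector — entry i is the
  sum of the 1-based positions at which residue i occurs, so the entries of a
  length-n sequence always total n(n+1)/2.
* ``raapiv``: the same computed on the reversed sequence.
* ``prim``: 20x20 position-relative incidence matrix; entry (i, j) accumulates
  the signed offsets of every occurrence of residue j relative to residue i
  (see ``PrimStrategy`` for the two reference conventions).
* ``rprim``: PRIM of the reversed sequence.

All encoders are pure and deterministic.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from bbbpep.sequences import AA_INDEX, Peptide


class PrimStrategy(str, Enum):
    """Reference-point convention for the incidence matrix.

    FIRST_OCCURRENCE: entry (i, j) = sum over positions q of residue j of
    (q - firstpos(i)); rows of absent residues are zero. This is the default.

    ALL_OCCURRENCES: entry (i, j) = sum over all pairs (p, q) with residue i
    at p and residue j at q of (q - p).
    """

    FIRST_OCCURRENCE = "first_occurrence"
    ALL_OCCURRENCES = "all_occurrences"


def _indices(p: Peptide) -> np.ndarray:
    return np.fromiter((AA_INDEX[ch] for ch in p.sequence), dtype=np.int64, count=len(p))


def frequency_vector(p: Peptide) -> np.ndarray:
    """Occurrence count of each canonical residue; entries sum to len(p)."""
    return np.bincount(_indices(p), minlength=20)


def aapiv(p: Peptide) -> np.ndarray:
    """Sum of 1-based positions per residue; entries total n(n+1)/2."""
    positions = np.arange(1, len(p) + 1, dtype=np.int64)
    return np.bincount(_indices(p), weights=positions, minlength=20).astype(np.int64)


def raapiv(p: Peptide) -> np.ndarray:
    """``aapiv`` of the reversed sequence."""
    return aapiv(p.reverse())


def prim(p: Peptide, strategy: PrimStrategy = PrimStrategy.FIRST_OCCURRENCE) -> np.ndarray:
    """20x20 position-relative incidence matrix (400 coefficients).

    Row i refers to residue i as the reference, column j to the target
    residue whose positions are accumulated. Rows of residues absent from
    the sequence are identically zero.
    """
    idx = _indices(p)
    positions = np.arange(1, len(p) + 1, dtype=np.int64)
    # per-residue position sums and counts (reused by both strategies)
    pos_sum = np.bincount(idx, weights=positions, minlength=20).astype(np.int64)
    count = np.bincount(idx, minlength=20)
    present = count > 0

    out = np.zeros((20, 20), dtype=np.int64)
    if strategy == PrimStrategy.FIRST_OCCURRENCE:
        first = np.full(20, -1, dtype=np.int64)
        for q, r in zip(positions[::-1], idx[::-1]):
            first[r] = q
        for i in range(20):
            if present[i]:
                out[i, :] = pos_sum - first[i] * count
        out[:, ~present] = 0
    elif strategy == PrimStrategy.ALL_OCCURRENCES:
        # sum over pairs (p, q): count_i * pos_sum_j - pos_sum_i * count_j
        out = np.outer(count, pos_sum) - np.outer(pos_sum, count)
        out[~present, :] = 0
        out[:, ~present] = 0
    else:  # pragma: no cover
        raise ValueError(f"unknown strategy {strategy!r}")
    return out


def rprim(p: Peptide, strategy: PrimStrategy = PrimStrategy.FIRST_OCCURRENCE) -> np.ndarray:
    """``prim`` of the reversed sequence."""
    return prim(p.reverse(), strategy)
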