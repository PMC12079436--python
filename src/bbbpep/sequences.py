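"""Peptide records, alphabet validation, and FASTA input/output.

The toolkit works exclusively with the 20 canonical amino acids; ambiguous
one-letter codes (B, J, O, U, X, Z) are rejected at construction time because
every downstream encoder indexes residues by their alphabetic ordinal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids in alphabetical one-letter order.
#: Index i of every 20-long feature block refers to CANONICAL_AA[i].
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Residue -> 0-based alphabetical index (A=0 ... Y=19).
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the canonical alphabet."""


def validate_sequence(sequence: str, record_id: str = "<anonymous>") -> str:
    """Uppercase *sequence* and verify it is non-empty canonical amino acids.

    Returns the normalized sequence. Raises :class:`SequenceValidationError`
    naming the record and the first offending character otherwise.
    """
    seq = sequence.upper()
    if len(seq) == 0:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    for ch in seq:
        if ch not in _CANONICAL_SET:
            raise SequenceValidationError(
                f"record {record_id!r}: non-canonical residue {ch!r} "
                f"(allowed: {CANONICAL_AA})"
            )
    return seq


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with identifier and optional binary label.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header token before the first whitespace).
    sequence : str
        Sequence over the 20 canonical one-letter codes. Lowercase input is
        uppercased; ambiguous codes raise :class:`SequenceValidationError`.
    label : int, optional
        1 for a blood-brain-barrier-penetrating peptide, 0 for a
        non-penetrating one, ``None`` when unknown.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, self.id))
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse(self) -> "Peptide":
        """The same peptide read C-terminus to N-terminus."""
        return Peptide(self.id, self.sequence[::-1], self.label)


@dataclass
class LabeledDataset:
    """An ordered collection of peptides in which every member carries a label."""

    peptides: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.peptides:
            if p.label is None:
                raise ValueError(f"record {p.id!r} has no label; LabeledDataset requires labels")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i):
        return self.peptides[i]

    @property
    def labels(self) -> list:
        return [p.label for p in self.peptides]

    @property
    def class_counts(self) -> tuple:
        """(positives, negatives); always sums to ``len(self)``."""
        pos = sum(1 for p in self.peptides if p.label == 1)
        return pos, len(self.peptides) - pos

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.peptides[i] for i in indices])


def read_fasta(path: os.PathLike | str, labels: Optional[dict] = None) -> list:
    """Read peptides from a FASTA file.

    Multi-line sequences are concatenated, lowercase is uppercased, and the
    header token before the first whitespace becomes the id. If *labels* maps
    ids to 0/1, the labels are attached.

    Raises
    ------
    FastaParseError
        If sequence data appears before any ``>`` header (with the line number).
    SequenceValidationError
        If a record contains a residue outside the canonical alphabet.
    """
    # Biopython silently ignores leading junk; enforce the structural contract
    # (no sequence before the first header) with an explicit pre-scan.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break

    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        label = labels.get(record.id) if labels is not None else None
        peptides.append(Peptide(record.id, str(record.seq), label))
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: os.PathLike | str) -> None:
    """Write peptides to *path* in FASTA format (one line per sequence).

    Round-trip contract: ``read_fasta`` on the written file reproduces the
    ids and sequences exactly.
    """
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def write_labels(dataset: LabeledDataset, path: os.PathLike | str) -> None:
    """Write a two-column TSV (id, label) companion file for a labeled set."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for p in dataset:
            fh.write(f"{p.id}\t{p.label}\n")


def read_labels(path: os.PathLike | str) -> dict:
    """Read a two-column (id, label) TSV written by :func:`write_labels`."""
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two tab-separated columns")
            out[parts[0]] = int(parts[1])
    return out
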