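import numpy as np
import pytest

from bbbpep.sequences import CANONICAL_AA, Peptide


def random_peptide(rng: np.random.Generator, min_len: int = 5, max_len: int = 40, ident: str = "p") -> Peptide:
    length = int(rng.integers(min_len, max_len + 1))
    seq = "".join(CANONICAL_AA[i] for i in rng.integers(0, 20, size=length))
    return Peptide(ident, seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_peptides(rng):
    """A deterministic batch of 50 random peptides."""
    return [random_peptide(rng, ident=f"p{i}") for i in range(50)]
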