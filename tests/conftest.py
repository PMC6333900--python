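import numpy as np
import pytest

from ngpd._codons import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_peptide(rng: np.random.Generator, length: int = 9) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
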