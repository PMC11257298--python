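import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from encap.peptides import LabeledPeptideSet, Peptide
from encap.tables import AMINO_ACIDS


def random_sequence(rng: np.random.Generator, lo: int = 8, hi: int = 14) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def random_peptides(rng) -> list[str]:
    """120 random peptides of lengths 8-14 for encoder-oracle comparisons."""
    return [random_sequence(rng) for _ in range(120)]


@pytest.fixture
def small_labeled_set(rng) -> LabeledPeptideSet:
    peptides = [Peptide(f"p{i}", random_sequence(rng)) for i in range(30)]
    labels = [i % 2 for i in range(30)]
    return LabeledPeptideSet(peptides, labels)
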