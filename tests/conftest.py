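import numpy as np
import pytest

from afpkit.compositions import PropertyTable
from afpkit.sequences import CANONICAL_ALPHABET, ProteinSequence
from afpkit.synthetic import (
    SyntheticSpec,
    disjoint_biases,
    generate_dataset,
)


@pytest.fixture(scope="session")
def props() -> PropertyTable:
    return PropertyTable.default()


def random_sequence(rng: np.random.Generator, length: int, seq_id: str = "r") -> ProteinSequence:
    letters = rng.choice(list(CANONICAL_ALPHABET), size=length)
    return ProteinSequence(id=seq_id, residues="".join(letters))


@pytest.fixture(scope="session")
def separable_dataset():
    """A perfectly separable two-class dataset: disjoint composition
    support, 50 sequences per class."""
    pos, neg = disjoint_biases()
    spec = SyntheticSpec(n_pos=50, n_neg=50, bias_pos=pos, bias_neg=neg, seed=11)
    seqs, labels, _ = generate_dataset(spec)
    return seqs, labels
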