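import numpy as np
import pytest

from ncrna_funclass.io import LabeledDataset, SequenceRecord


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Six short labeled sequences over three classes."""
    rows = [
        ("t1", "ACGTACGTACGTACGT", "tRNA"),
        ("t2", "ACGTACGAACGTACGT", "tRNA"),
        ("m1", "GGGGCCCCGGGGCCCC", "miRNA"),
        ("m2", "GGGGCCCAGGGGCCCC", "miRNA"),
        ("r1", "TTTTAAAATTTTAAAA", "rRNA"),
        ("r2", "TTTTAAATTTTTAAAA", "rRNA"),
    ]
    records = [SequenceRecord(id=i, seq=s, label=c) for i, s, c in rows]
    return LabeledDataset(records, classes=sorted({c for _, _, c in rows}))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
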