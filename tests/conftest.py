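import numpy as np
import pytest

from airliner.io_genomics import SequenceWindow

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def naive_revcomp(seq: str) -> str:
    """Character-by-character reverse complement, independent of Biopython."""
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def naive_iupac_count(sequence: str, consensus: str) -> int:
    """Position-by-position O(n*w) scan counting overlapping matches."""
    w = len(consensus)
    count = 0
    for p in range(len(sequence) - w + 1):
        if all(sequence[p + k] in IUPAC_SETS[consensus[k]] for k in range(w)):
            count += 1
    return count


def window(seq: str, label: str = "unknown") -> SequenceWindow:
    """Build a SequenceWindow from an odd-length A-centered string."""
    assert len(seq) % 2 == 1
    return SequenceWindow(seq.upper(), len(seq) // 2, label=label)


def random_windows(rng: np.random.Generator, n: int, radius: int, label: str):
    """Uniform random A-centered windows."""
    width = 2 * radius + 1
    out = []
    for _ in range(n):
        chars = rng.choice(list("ACGT"), size=width)
        chars[radius] = "A"
        out.append(SequenceWindow("".join(chars), radius, label=label))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
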