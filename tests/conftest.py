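import numpy as np
import pytest

from motifsig import (SequenceRecord, SequenceSet, build_catalog,
                      concat_sets, default_catalog)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def tiny_sets():
    """Two positives and two negatives with distinct composition."""
    pos = SequenceSet(
        [
            SequenceRecord("p1", "ACGTACGTACGT", class_label="positive"),
            SequenceRecord("p2", "CGCGCGCGCGCG", class_label="positive"),
        ],
        name="pos",
    )
    neg = SequenceSet(
        [
            SequenceRecord("n1", "AAAATTTTAAAA", class_label="negative"),
            SequenceRecord("n2", "TTTTAAAATTTT", class_label="negative"),
        ],
        name="neg",
    )
    return pos, neg


def random_dna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def naive_encode(seq: str, catalog, denominator: str = "length"):
    """Independent sliding-window recount of every catalog feature."""
    L = len(seq)
    counts: dict[str, int] = {}
    for k in (1, 2, 3, 4):
        for i in range(L - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1

    def denom(k):
        return L if denominator == "length" else L - k + 1

    out = np.zeros(len(catalog))
    for j, entry in enumerate(catalog.entries):
        if entry.category == "aggregate":
            x, y = entry.motif
            out[j] = (counts.get(x, 0) + counts.get(y, 0)) / denom(1)
        else:
            k = len(entry.motif)
            out[j] = counts.get(entry.motif, 0) / denom(k)
    return out
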