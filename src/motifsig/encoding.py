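"""346-dimensional motif-frequency encoding of DNA sequences.

Every sequence is represented by the frequencies of all short motifs up to
length four, grouped in five categories:

* 4 single-nucleotide frequencies (A, C, G, T),
* 6 aggregate two-base frequencies (A+C, A+G, A+T, C+G, C+T, G+T — the
  unordered base pairs; each is the sum of the two mono frequencies),
* 16 dinucleotide, 64 trinucleotide and 256 tetranucleotide frequencies in
  lexicographic order,

for a total of 4 + 6 + 16 + 64 + 256 = 346 features.  All counts are
normalized by the sequence length L (not by the number of k-mer windows
L-k+1), so that values are comparable across sequences of different
lengths; the window-count denominator is available via
``denominator="windows"``.  Windows containing ``N`` contribute to no
k-mer count and the denominator is not adjusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_CODE = {ord(b): i for i, b in enumerate(BASES)}

CATEGORIES = ("mono", "aggregate", "di", "tri", "tetra")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One catalog entry: a k-mer or an aggregate base pair."""

    name: str
    category: str
    motif: str  # the k-mer itself, or "XY" for aggregate X+Y


@dataclass(frozen=True)
class FeatureCatalog:
    """The canonical ordered list of the 346 motif features."""

    entries: tuple[FeatureDescriptor, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def index_of(self, name: str) -> int:
        try:
            return self._name_index()[name]
        except KeyError:
            raise KeyError(f"unknown feature name {name!r}") from None

    def _name_index(self) -> dict[str, int]:
        # frozen dataclass: cache on the object dict via object.__setattr__
        cached = self.__dict__.get("_idx")
        if cached is None:
            cached = {e.name: i for i, e in enumerate(self.entries)}
            object.__setattr__(self, "_idx", cached)
        return cached

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            counts[e.category] += 1
        return counts


def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def build_catalog() -> FeatureCatalog:
    """Build the canonical 346-entry catalog.

    Order: mono A,C,G,T; aggregates A+C, A+G, A+T, C+G, C+T, G+T; then
    di-, tri- and tetranucleotides each in lexicographic order.
    """
    entries: list[FeatureDescriptor] = []
    for b in BASES:
        entries.append(FeatureDescriptor(b, "mono", b))
    for x, y in itertools.combinations(BASES, 2):
        entries.append(FeatureDescriptor(f"{x}+{y}", "aggregate", x + y))
    for k, cat in ((2, "di"), (3, "tri"), (4, "tetra")):
        for km in _kmers(k):
            entries.append(FeatureDescriptor(km, cat, km))
    assert len(entries) == 346
    return FeatureCatalog(tuple(entries))


_DEFAULT_CATALOG: FeatureCatalog | None = None


def default_catalog() -> FeatureCatalog:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = build_catalog()
    return _DEFAULT_CATALOG


def _seq_codes(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0,C=1,G=2,T=3, N=-1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for byte, code in ((65, 0), (67, 1), (71, 2), (84, 3)):  # A C G T
        codes[arr == byte] = code
    return codes


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Count all 4**k k-mers over valid (N-free) windows."""
    n_win = codes.size - k + 1
    if n_win <= 0:
        return np.zeros(4**k, dtype=np.int64)
    window_code = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        col = codes[j : j + n_win]
        valid &= col >= 0
        window_code = window_code * 4 + np.where(col >= 0, col, 0)
    return np.bincount(window_code[valid], minlength=4**k)


def encode(
    seq: str,
    catalog: FeatureCatalog | None = None,
    denominator: str = "length",
) -> np.ndarray:
    """Encode one sequence into the 346-dimensional frequency vector.

    Parameters
    ----------
    seq : str
        DNA over ``{A,C,G,T,N}``, length >= 4.
    catalog : FeatureCatalog, optional
        Defines column order; defaults to the canonical catalog.
    denominator : {"length", "windows"}
        Normalizer for k-mer counts: the sequence length L (default) or
        the window count L-k+1.

    Returns
    -------
    numpy.ndarray of shape (346,), all values in [0, 1] (an aggregate
    X+Y is the sum of two mono frequencies, which itself cannot exceed 1).
    """
    if catalog is None:
        catalog = default_catalog()
    L = len(seq)
    if L < 4:
        raise ValueError(
            f"sequence of length {L} < 4: tetranucleotide features "
            "cannot be populated"
        )
    if denominator not in ("length", "windows"):
        raise ValueError(f"unknown denominator {denominator!r}")
    codes = _seq_codes(seq)
    if np.any((codes < -1) | (codes > 3)):  # pragma: no cover - guarded upstream
        raise ValueError("sequence contains characters outside A,C,G,T,N")

    out = np.empty(len(catalog), dtype=np.float64)
    mono = _kmer_counts(codes, 1)
    counts = {1: mono}
    for k in (2, 3, 4):
        counts[k] = _kmer_counts(codes, k)

    def denom(k: int) -> float:
        return float(L) if denominator == "length" else float(L - k + 1)

    mono_freq = mono / denom(1)
    out[0:4] = mono_freq
    # aggregates: unordered pairs in combination order
    agg_pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for i, (a, b) in enumerate(agg_pairs):
        out[4 + i] = mono_freq[a] + mono_freq[b]
    offset = 10
    for k in (2, 3, 4):
        out[offset : offset + 4**k] = counts[k] / denom(k)
        offset += 4**k
    return out


@dataclass
class FeatureMatrix:
    """Encoded sequence set: rows = sequences, columns = catalog features."""

    row_ids: list[str]
    labels: np.ndarray  # shape (n,), values in {0, 1}; 1 = positive
    values: np.ndarray  # shape (n, n_features)
    catalog: FeatureCatalog = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.row_ids)
        if self.values.shape != (n, len(self.catalog)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} rows x {len(self.catalog)} catalog features"
            )
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.catalog.names)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.row_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 catalog: FeatureCatalog | None = None) -> "FeatureMatrix":
        catalog = catalog or default_catalog()
        df = pd.read_csv(path, sep="\t")
        missing = [n for n in catalog.names if n not in df.columns]
        if missing:
            raise ValueError(f"matrix file lacks columns: {missing[:5]}...")
        return cls(
            row_ids=df["id"].astype(str).tolist(),
            labels=df["label"].to_numpy(),
            values=df[catalog.names].to_numpy(dtype=np.float64),
            catalog=catalog,
        )


_LABEL_TO_INT = {"positive": 1, "negative": 0}


def encode_set(
    seqs,
    catalog: FeatureCatalog | None = None,
    denominator: str = "length",
) -> FeatureMatrix:
    """Encode a SequenceSet into a :class:`FeatureMatrix`.

    Row order preserves input order; labels are taken from each record's
    ``class_label`` (which must be set on every record).
    """
    catalog = catalog or default_catalog()
    records = list(seqs)
    if not records:
        raise ValueError("no sequences to encode")
    labels = np.empty(len(records), dtype=np.int64)
    values = np.empty((len(records), len(catalog)), dtype=np.float64)
    for i, rec in enumerate(records):
        if rec.class_label is None:
            raise ValueError(f"record {rec.id!r} lacks a class_label")
        labels[i] = _LABEL_TO_INT[rec.class_label]
        values[i] = encode(rec.seq, catalog, denominator=denominator)
    return FeatureMatrix(
        row_ids=[r.id for r in records],
        labels=labels,
        values=values,
        catalog=catalog,
    )


def concat_sets(positives, negatives, catalog: FeatureCatalog | None = None,
                denominator: str = "length") -> FeatureMatrix:
    """Encode a positive and a negative SequenceSet into one matrix."""
    from .sequence_io import SequenceSet

    pos = positives.relabel("positive")
    neg = negatives.relabel("negative")
    merged = SequenceSet(list(pos.records) + list(neg.records),
                         name=f"{positives.name}+{negatives.name}")
    return encode_set(merged, catalog, denominator=denominator)
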