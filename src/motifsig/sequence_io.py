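"""Reading, writing and filtering of labeled DNA sequence sets.

Sequence sets are the carrier type for enhancer candidates throughout the
pipeline.  Sequences are uppercased on ingest and restricted to the
{A, C, G, T, N} alphabet; anything else is coerced to ``N`` (real genome
dumps contain IUPAC ambiguity codes and soft-masked stretches, which we do
not want to reject outright).  BED intervals follow the standard 0-based
half-open convention and sequences are always extracted from the + strand:
transcribed enhancers are bidirectionally transcribed, so there is no
natural orientation to apply at ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence with optional provenance labels.

    Parameters
    ----------
    id : str
        Unique identifier within a :class:`SequenceSet`.
    seq : str
        DNA sequence over ``{A, C, G, T, N}`` (validated).
    facet : str, optional
        Cell type / tissue label of origin.
    class_label : {"positive", "negative"}, optional
        Supervised class assignment.
    chrom, start, end : optional
        Genomic interval of origin (0-based half-open), when known.
    """

    id: str
    seq: str
    facet: str | None = None
    class_label: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)}; "
                "sequences must be uppercase over A,C,G,T,N"
            )
        if self.class_label not in (None, "positive", "negative"):
            raise ValueError(f"invalid class_label {self.class_label!r}")

    @property
    def interval(self) -> tuple[str, int, int] | None:
        if self.chrom is None or self.start is None or self.end is None:
            return None
        return (self.chrom, self.start, self.end)

    def with_label(self, class_label: str) -> "SequenceRecord":
        return replace(self, class_label=class_label)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def relabel(self, class_label: str) -> "SequenceSet":
        """Return a copy with every record assigned ``class_label``."""
        return SequenceSet(
            [r.with_label(class_label) for r in self.records], name=self.name
        )


def _clean_sequence(raw: str) -> tuple[str, int]:
    """Uppercase and coerce non-ACGTN characters to N; count coercions."""
    up = raw.upper()
    cleaned = up.translate({ord(c): "N" for c in set(up) - VALID_ALPHABET})
    n_coerced = sum(a != b for a, b in zip(up, cleaned))
    return cleaned, n_coerced


def read_fasta(path: str | Path, name: str | None = None) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace becomes the record id.
    Characters outside ``{A,C,G,T,N}`` are mapped to ``N``; a single
    warning reports the total count.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On an empty file or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    total_coerced = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        seq, n_coerced = _clean_sequence(str(entry.seq))
        total_coerced += n_coerced
        records.append(SequenceRecord(id=entry.id, seq=seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    if total_coerced:
        logger.warning(
            "%s: coerced %d non-ACGTN characters to N", path, total_coerced
        )
    return SequenceSet(records, name=name or path.stem)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    """Write a :class:`SequenceSet` as FASTA (fixed line width)."""
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description="") for r in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _parse_bed_line(line: str, lineno: int) -> tuple[str, int, int, str | None]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise ValueError(f"BED line {lineno}: expected >= 3 columns")
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
    if start < 0 or end <= start:
        raise ValueError(
            f"BED line {lineno}: invalid interval {chrom}:{start}-{end}"
        )
    return chrom, start, end, name


def read_bed_extract(
    bed_path: str | Path, genome_fasta: str | Path, name: str | None = None
) -> SequenceSet:
    """Extract + strand sequences for BED intervals from a genome FASTA.

    Intervals are 0-based half-open.  The record id is the BED name column
    when present, otherwise ``"chrom:start-end"``.

    Raises
    ------
    ValueError
        For unknown contigs or intervals beyond contig bounds (the
        offending interval is named in the message).
    """
    bed_path = Path(bed_path)
    if not bed_path.exists():
        raise FileNotFoundError(f"BED file not found: {bed_path}")
    genome = Fasta(str(genome_fasta))
    records: list[SequenceRecord] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, bed_name = _parse_bed_line(line, lineno)
            if chrom not in genome:
                raise ValueError(f"unknown contig {chrom!r} in {bed_path}")
            contig_len = len(genome[chrom])
            if end > contig_len:
                raise ValueError(
                    f"interval {chrom}:{start}-{end} exceeds contig "
                    f"length {contig_len}"
                )
            raw = genome[chrom][start:end].seq
            seq, _ = _clean_sequence(raw)
            rec_id = bed_name or f"{chrom}:{start}-{end}"
            records.append(
                SequenceRecord(
                    id=rec_id, seq=seq, chrom=chrom, start=start, end=end
                )
            )
    if not records:
        raise ValueError(f"no intervals in {bed_path}")
    return SequenceSet(records, name=name or bed_path.stem)


def _overlaps(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    # half-open intervals share a base iff they are on the same contig and
    # neither ends before the other starts
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def filter_overlap(
    query: SequenceSet,
    exclusion: Iterable[tuple[str, int, int]] | SequenceSet,
) -> SequenceSet:
    """Drop query records whose interval overlaps any exclusion interval.

    Overlap means sharing at least one base under half-open coordinates.
    Every query record must carry interval metadata.
    """
    if isinstance(exclusion, SequenceSet):
        excl = []
        for rec in exclusion:
            if rec.interval is None:
                raise ValueError(
                    f"exclusion record {rec.id!r} lacks interval metadata"
                )
            excl.append(rec.interval)
    else:
        excl = list(exclusion)
    kept = []
    for rec in query:
        if rec.interval is None:
            raise ValueError(f"record {rec.id!r} lacks interval metadata")
        if not any(_overlaps(rec.interval, e) for e in excl):
            kept.append(rec)
    return SequenceSet(kept, name=query.name)
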