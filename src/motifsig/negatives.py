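"""Negative-control construction for transcribed-enhancer classification.

Two constructions are supported:

1. *Random controls*: one negative per positive, obtained by random
   single-nucleotide substitution of the positive sequence.  Point
   mutations are known to disrupt enhancer activity, so a mutated copy is
   a plausible non-enhancer with matched length and (approximately)
   matched base composition.  Candidates identical to any sequence in the
   known-positive universe are rejected and regenerated.
2. *One-vs-all sets*: for a target cell type/tissue (facet), positives
   are its exclusively transcribed enhancers and negatives are the
   exclusively transcribed enhancers of every other facet.

The per-base substitution probability is configurable (default 0.1) and
each substituted base is drawn uniformly from the three alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .sequence_io import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationConfig:
    """Parameters of the mutation-based negative generator.

    substitution_rate : per-base substitution probability, in (0, 1].
    seed : RNG seed for reproducibility.
    max_retries : attempts per sequence before giving up when candidates
        keep colliding with the positive universe.
    """

    substitution_rate: float = 0.1
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.substitution_rate <= 1.0):
            raise ValueError(
                "substitution_rate must be in (0, 1]; a rate of 0 can "
                "never produce a valid negative"
            )
        if self.max_retries < 1:
            raise ValueError("max_retries must be positive")


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    """Substitute each non-N position independently with probability ``rate``.

    A substituted base is drawn uniformly from the three alternative
    bases, so at rate 1.0 no position keeps its original base.  ``N``
    positions are left untouched and length is preserved.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for byte, code in ((65, 0), (67, 1), (71, 2), (84, 3)):
        codes[arr == byte] = code
    eligible = codes >= 0
    hit = eligible & (rng.random(arr.shape) < rate)
    n_hit = int(hit.sum())
    if n_hit:
        # adding 1..3 mod 4 maps a base uniformly onto the other three
        shift = rng.integers(1, 4, size=n_hit)
        new_codes = (codes[hit] + shift) % 4
        arr[hit] = _CODE_TO_BASE[new_codes]
    return arr.tobytes().decode("ascii")


def make_random_controls(
    positives: SequenceSet,
    universe: SequenceSet,
    cfg: MutationConfig,
) -> SequenceSet:
    """Generate one mutated negative per positive sequence.

    ``universe`` is the exclusion superset: any candidate whose sequence
    string exactly matches a universe sequence is rejected and
    regenerated, up to ``cfg.max_retries`` times.

    Returns a SequenceSet of the same size as ``positives`` with ids
    ``"<source_id>__neg"`` and ``class_label="negative"``.
    """
    rng = np.random.default_rng(cfg.seed)
    forbidden = frozenset(universe.sequences)
    out: list[SequenceRecord] = []
    for rec in positives:
        candidate = None
        for _ in range(cfg.max_retries):
            trial = mutate_sequence(rec.seq, cfg.substitution_rate, rng)
            if trial not in forbidden:
                candidate = trial
                break
        if candidate is None:
            raise RuntimeError(
                f"could not generate a negative for {rec.id!r} outside the "
                f"positive universe in {cfg.max_retries} attempts"
            )
        out.append(
            SequenceRecord(
                id=f"{rec.id}__neg",
                seq=candidate,
                facet=rec.facet,
                class_label="negative",
            )
        )
    return SequenceSet(out, name=f"{positives.name}_random_controls")


def find_exclusive(
    all_facets: Mapping[str, SequenceSet]
) -> dict[str, SequenceSet]:
    """Per facet, the records whose id appears in no other facet.

    Membership across facets is determined by record id; coordinate-style
    ids make identical genomic intervals collide as intended.
    """
    counts: dict[str, int] = {}
    for seqs in all_facets.values():
        for rec in seqs:
            counts[rec.id] = counts.get(rec.id, 0) + 1
    exclusive: dict[str, SequenceSet] = {}
    for facet, seqs in all_facets.items():
        recs = [r for r in seqs if counts[r.id] == 1]
        exclusive[facet] = SequenceSet(recs, name=f"{facet}_exclusive")
    return exclusive


def make_one_vs_all(
    exclusive_sets: Mapping[str, SequenceSet],
    target_facet: str,
    min_size: int = 5,
) -> tuple[SequenceSet, SequenceSet]:
    """One-vs-all split: target facet's exclusive enhancers vs all others.

    Facets with fewer than ``min_size`` exclusively transcribed enhancers
    are rejected (too few samples to train on).
    """
    if target_facet not in exclusive_sets:
        raise KeyError(f"facet {target_facet!r} not present")
    pos = exclusive_sets[target_facet]
    if len(pos) < min_size:
        raise ValueError(
            f"insufficient exclusive enhancers for facet {target_facet!r}: "
            f"{len(pos)} < {min_size}"
        )
    neg_records: list[SequenceRecord] = []
    for facet, seqs in exclusive_sets.items():
        if facet == target_facet:
            continue
        neg_records.extend(r.with_label("negative") for r in seqs)
    positives = pos.relabel("positive")
    negatives = SequenceSet(neg_records, name=f"not_{target_facet}")
    return positives, negatives
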