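"""Synthetic enhancer-like datasets with controllable planted motif signal.

The generator emulates the structure of CAGE-defined enhancer facet data
without any external download: positives are drawn from an i.i.d.
background nucleotide model with short planted motifs inserted at
enriched rates; negatives are either pure background draws or mutated
copies of the positives.  Ground-truth planted motifs are attached so
signature-recovery can be scored.

Insertion model: for a planted k-mer with enrichment multiplier ``e``,
the number of inserted copies per positive sequence is
``Poisson((e - 1) * E_bg)`` where ``E_bg = (L - k + 1) * P_bg(kmer)`` is
the expected background occurrence count.  Inserted copies overwrite the
background at uniformly chosen non-overlapping positions, so the total
expected occurrence count is approximately ``e * E_bg`` and an
enrichment of 1 inserts nothing (exact null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .negatives import MutationConfig, make_random_controls
from .sequence_io import SequenceRecord, SequenceSet

BASES = "ACGT"

#: study-scale defaults: 300 sequences per class at enhancer-scale
#: length 300 bp over a uniform background
DEFAULT_N = 300
DEFAULT_LENGTH = 300


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic facet dataset.

    planted_motifs : motifs (with enrichment multiplier >= 1) planted in
        the positives of every facet.
    facet_private_motifs : per-facet motifs planted only in that facet's
        positives (at ``private_enrichment``).
    negative_mode : "background" draws negatives from the background
        model; "mutate" derives them by random substitution of the
        positives (rate ``mutation_rate``).
    """

    n_pos: int = DEFAULT_N
    n_neg: int = DEFAULT_N
    length: int = DEFAULT_LENGTH
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_motifs: tuple[tuple[str, float], ...] = ()
    n_facets: int = 1
    facet_private_motifs: Mapping[str, Sequence[str]] | None = None
    private_enrichment: float = 5.0
    negative_mode: str = "background"
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        for kmer, mult in self.planted_motifs:
            if mult < 1.0:
                raise ValueError(
                    f"enrichment multiplier for {kmer!r} must be >= 1"
                )
            if len(kmer) > self.length:
                raise ValueError(
                    f"motif {kmer!r} longer than sequence length "
                    f"{self.length}"
                )
        if self.negative_mode not in ("background", "mutate"):
            raise ValueError(f"unknown negative_mode {self.negative_mode!r}")

    def facet_names(self) -> list[str]:
        if self.facet_private_motifs:
            return list(self.facet_private_motifs)
        return [f"facet{i+1}" for i in range(self.n_facets)]


@dataclass
class SimulatedData:
    """Facet datasets plus the ground-truth planted motif lists."""

    facets: dict[str, tuple[SequenceSet, SequenceSet]]
    shared_truth: list[str]
    facet_truth: dict[str, list[str]]

    def truth_for(self, facet: str) -> list[str]:
        return self.shared_truth + self.facet_truth.get(facet, [])


def _background_expected_count(
    kmer: str, length: int, background: Sequence[float]
) -> float:
    p = 1.0
    for b in kmer:
        p *= background[BASES.index(b)]
    return (length - len(kmer) + 1) * p


def _draw_background(
    n: int, length: int, background: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    return rng.choice(4, size=(n, length), p=np.asarray(background))


def _plant(
    row: np.ndarray,
    motifs: Sequence[tuple[str, float]],
    background: Sequence[float],
    rng: np.random.Generator,
) -> None:
    """Overwrite background with planted motifs at non-overlapping spots."""
    length = row.size
    occupied = np.zeros(length, dtype=bool)
    for kmer, mult in motifs:
        k = len(kmer)
        lam = (mult - 1.0) * _background_expected_count(
            kmer, length, background
        )
        n_insert = rng.poisson(lam)
        codes = np.array([BASES.index(b) for b in kmer])
        placed = 0
        attempts = 0
        while placed < n_insert and attempts < 50 * (n_insert + 1):
            attempts += 1
            pos = rng.integers(0, length - k + 1)
            if occupied[pos : pos + k].any():
                continue
            row[pos : pos + k] = codes
            occupied[pos : pos + k] = True
            placed += 1


_CODE_TO_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rows_to_seqs(rows: np.ndarray) -> list[str]:
    return [
        _CODE_TO_CHAR[row].tobytes().decode("ascii") for row in rows
    ]


def simulate_dataset(cfg: SimConfig) -> SimulatedData:
    """Generate labeled positive/negative sequence sets per facet.

    Deterministic given ``cfg.seed``: same config, byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    private = {
        facet: list(motifs)
        for facet, motifs in (cfg.facet_private_motifs or {}).items()
    }
    facets: dict[str, tuple[SequenceSet, SequenceSet]] = {}
    for facet in cfg.facet_names():
        pos_rows = _draw_background(
            cfg.n_pos, cfg.length, cfg.background, rng
        )
        motifs = list(cfg.planted_motifs) + [
            (m, cfg.private_enrichment) for m in private.get(facet, [])
        ]
        for kmer, _ in motifs:
            if len(kmer) > cfg.length:
                raise ValueError(
                    f"motif {kmer!r} longer than sequence length"
                )
        for row in pos_rows:
            _plant(row, motifs, cfg.background, rng)
        pos = SequenceSet(
            [
                SequenceRecord(
                    id=f"{facet}_pos{i}", seq=s, facet=facet,
                    class_label="positive",
                )
                for i, s in enumerate(_rows_to_seqs(pos_rows))
            ],
            name=f"{facet}_pos",
        )
        if cfg.negative_mode == "background":
            neg_rows = _draw_background(
                cfg.n_neg, cfg.length, cfg.background, rng
            )
            neg = SequenceSet(
                [
                    SequenceRecord(
                        id=f"{facet}_neg{i}", seq=s, facet=facet,
                        class_label="negative",
                    )
                    for i, s in enumerate(_rows_to_seqs(neg_rows))
                ],
                name=f"{facet}_neg",
            )
        else:
            mut_seed = int(rng.integers(0, 2**31 - 1))
            neg = make_random_controls(
                pos, universe=pos,
                cfg=MutationConfig(
                    substitution_rate=cfg.mutation_rate, seed=mut_seed
                ),
            )
        facets[facet] = (pos, neg)
    return SimulatedData(
        facets=facets,
        shared_truth=[kmer for kmer, _ in cfg.planted_motifs],
        facet_truth=private,
    )


def score_recovery(result, truth: Sequence[str]) -> float:
    """Fraction of planted motifs recovered by a selection result.

    For a SignatureResult, a motif counts as recovered when it appears in
    the selected signature; for a RankedFeatures, when it appears within
    the top 3*|truth| ranks.
    """
    if not truth:
        raise ValueError("truth motif list must be non-empty")
    if hasattr(result, "selected_features"):
        pool = set(result.selected_features)
    elif hasattr(result, "names"):
        pool = set(result.names[: 3 * len(truth)])
    else:
        raise TypeError(
            "result must be a SignatureResult or RankedFeatures"
        )
    hits = sum(1 for m in truth if m in pool)
    return hits / len(truth)
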