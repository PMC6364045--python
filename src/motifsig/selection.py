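"""Greedy motif-signature selection (phase 1 + phase 2 composition).

Features ranked by the Gini index are considered independently, which
can be suboptimal for classification; the greedy mitigation is to
evaluate the nested family of top-K ranked prefixes (K = 1..k_max) and
select the prefix whose mean MCC across repeated random splits is
maximal.  Ties are broken toward the smaller K (the simpler signature).
Only ranked prefixes are evaluated — never all subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .encoding import FeatureMatrix, concat_sets
from .evaluation import (METRIC_NAMES, SplitProtocol, SubsetEvaluation,
                         evaluate_subset)
from .ranking import RankedFeatures, gini_rank

logger = logging.getLogger(__name__)


@dataclass
class SignatureResult:
    """The selected motif combination and the per-K evaluation table."""

    selected_k: int
    selected_features: list[str]
    per_k: pd.DataFrame  # index K; columns <metric>_mean, <metric>_sd
    protocol: SplitProtocol
    ranking: RankedFeatures = field(repr=False)

    @property
    def selected_mean(self) -> dict[str, float]:
        row = self.per_k.loc[self.selected_k]
        return {m: float(row[f"{m}_mean"]) for m in METRIC_NAMES}

    def to_dict(self) -> dict:
        return {
            "selected_k": self.selected_k,
            "selected_features": self.selected_features,
            "protocol": {
                "train_fraction": self.protocol.train_fraction,
                "n_runs": self.protocol.n_runs,
                "stratified": self.protocol.stratified,
                "seed": self.protocol.seed,
            },
            "metrics": {
                m: {
                    "mean": float(self.per_k.loc[self.selected_k, f"{m}_mean"]),
                    "sd": float(self.per_k.loc[self.selected_k, f"{m}_sd"]),
                }
                for m in METRIC_NAMES
            },
        }


def select_signature(
    matrix: FeatureMatrix,
    ranking: RankedFeatures,
    protocol: SplitProtocol,
    k_max: int = 346,
) -> SignatureResult:
    """Evaluate top-K ranked prefixes and select the MCC-maximizing one.

    Each prefix is evaluated with fresh independent splits (seeded
    deterministically per K from ``protocol.seed``); the selected K is
    the argmax of mean MCC, ties broken toward smaller K.
    """
    if k_max < 1 or k_max > ranking.order.size:
        raise ValueError(
            f"k_max must be in [1, {ranking.order.size}], got {k_max}"
        )
    # disjoint, deterministic seed stream per candidate prefix
    k_seeds = np.random.SeedSequence(protocol.seed).spawn(k_max)
    rows = []
    best_k, best_mcc = None, -np.inf
    for k in range(1, k_max + 1):
        proto_k = SplitProtocol(
            train_fraction=protocol.train_fraction,
            n_runs=protocol.n_runs,
            stratified=protocol.stratified,
            seed=int(k_seeds[k - 1].generate_state(1)[0] % (2**31)),
        )
        ev = evaluate_subset(matrix, ranking.top(k), proto_k)
        row: dict[str, float] = {"K": k}
        for m in METRIC_NAMES:
            row[f"{m}_mean"] = ev.mean[m]
            row[f"{m}_sd"] = ev.sd[m]
        rows.append(row)
        if ev.mean["mcc"] > best_mcc:
            best_mcc = ev.mean["mcc"]
            best_k = k
    per_k = pd.DataFrame(rows).set_index("K")
    assert best_k is not None
    return SignatureResult(
        selected_k=best_k,
        selected_features=ranking.names[:best_k],
        per_k=per_k,
        protocol=protocol,
        ranking=ranking,
    )


def run_signature_pipeline(
    positives,
    negatives,
    protocol: SplitProtocol,
    k_max: int = 346,
    n_bins: int = 10,
    catalog=None,
) -> SignatureResult:
    """Encode, rank, and select a signature for one positive/negative pair."""
    matrix = concat_sets(positives, negatives, catalog=catalog)
    ranking = gini_rank(matrix, n_bins=n_bins)
    k_max = min(k_max, ranking.order.size)
    return select_signature(matrix, ranking, protocol, k_max=k_max)


@dataclass
class AtlasResult:
    """Per-facet signatures plus the cross-facet selection-frequency table."""

    signatures: dict[str, SignatureResult]
    selection_frequency: pd.Series  # feature -> fraction of facets selecting it
    failures: dict[str, str]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for facet, sig in self.signatures.items():
            mean = sig.selected_mean
            rows.append(
                {
                    "facet": facet,
                    "selected_k": sig.selected_k,
                    **{f"mean_{m}": mean[m] for m in METRIC_NAMES},
                }
            )
        return pd.DataFrame(rows)


def selection_frequency(
    signatures: Mapping[str, SignatureResult], all_features: list[str]
) -> pd.Series:
    """Fraction of facets whose signature contains each feature."""
    n = len(signatures)
    counts = {f: 0 for f in all_features}
    for sig in signatures.values():
        for f in sig.selected_features:
            counts[f] += 1
    return pd.Series(
        {f: c / n for f, c in counts.items()}, name="selection_frequency"
    )


def run_facet_atlas(
    facet_data: Mapping[str, tuple],
    protocol: SplitProtocol,
    k_max: int = 346,
    n_bins: int = 10,
    catalog=None,
) -> AtlasResult:
    """Independent signature selection per facet.

    ``facet_data`` maps facet name to a (positives, negatives) pair of
    SequenceSets.  Per-facet failures are recorded and the atlas
    continues; an empty facet map is an error.
    """
    if not facet_data:
        raise ValueError("empty facet map")
    signatures: dict[str, SignatureResult] = {}
    failures: dict[str, str] = {}
    feature_names: list[str] | None = None
    for facet, (pos, neg) in facet_data.items():
        try:
            sig = run_signature_pipeline(
                pos, neg, protocol, k_max=k_max, n_bins=n_bins,
                catalog=catalog,
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("facet %s failed: %s", facet, exc)
            failures[facet] = str(exc)
            continue
        signatures[facet] = sig
        if feature_names is None:
            feature_names = list(sig.ranking.names)
    if not signatures:
        raise RuntimeError(f"all facets failed: {failures}")
    freq = selection_frequency(signatures, sorted(feature_names))
    return AtlasResult(
        signatures=signatures, selection_frequency=freq, failures=failures
    )
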