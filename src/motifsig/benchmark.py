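"""Benchmark harness: compare motif sets with independent classifiers.

Motif sets selected with one classifier may be biased toward it, so the
harness evaluates arbitrary feature subsets with K-nearest neighbors
(KNN) and bagged decision trees (BDT) — classifiers not used in
selection.  For each classifier a parameter grid is tuned by mean GM on
a tuning pass, then the best parameter is evaluated over the full
repeated-split protocol (60% training, 100 runs by default).  The
Vargha–Delaney A statistic quantifies the practical size of small
performance differences between two samples of per-run metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .encoding import FeatureCatalog, FeatureMatrix, default_catalog
from .evaluation import SplitProtocol, evaluate_subset

logger = logging.getLogger(__name__)

#: default grids: neighbor counts for KNN, tree counts for BDT
DEFAULT_KNN_GRID = (3, 4, 5, 6, 7, 8, 20)
DEFAULT_BDT_GRID = (20, 30, 40, 50, 60, 70, 150)


@dataclass(frozen=True)
class BenchmarkConfig:
    knn_grid: tuple[int, ...] = DEFAULT_KNN_GRID
    bdt_grid: tuple[int, ...] = DEFAULT_BDT_GRID
    split: SplitProtocol = field(
        default_factory=lambda: SplitProtocol(train_fraction=0.6, n_runs=100)
    )
    tuning_runs: int | None = None  # None -> same as split.n_runs
    standardize: bool = False  # z-score features before KNN distances

    def __post_init__(self) -> None:
        if not self.knn_grid or not self.bdt_grid:
            raise ValueError("classifier grids must be non-empty")


def resolve_motif_names(
    names: Sequence[str], catalog: FeatureCatalog | None = None
) -> np.ndarray:
    """Map feature-name tokens to catalog column indices.

    Tokens matching catalog names map directly; bare k-mers of length
    1-4 over ACGT map to the corresponding frequency feature.  Unknown
    tokens raise a ValueError listing all of them.
    """
    catalog = catalog or default_catalog()
    idx = []
    unknown = []
    for tok in names:
        t = tok.strip().upper()
        if not t:
            continue
        try:
            idx.append(catalog.index_of(t))
        except KeyError:
            unknown.append(tok)
    if unknown:
        raise ValueError(f"unknown feature names: {unknown}")
    if not idx:
        raise ValueError("empty motif set")
    return np.asarray(idx, dtype=np.int64)


def load_motif_file(
    path: str | Path, catalog: FeatureCatalog | None = None
) -> np.ndarray:
    """Load a plain-text motif set: one feature name or k-mer per line."""
    tokens = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return resolve_motif_names(tokens, catalog)


def _knn_factory(k: int, standardize: bool):
    def factory(rng: np.random.Generator):
        return _SklearnScorer(
            KNeighborsClassifier(n_neighbors=k), standardize
        )

    return factory


def _bdt_factory(n_trees: int, standardize: bool):
    def factory(rng: np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
        return _SklearnScorer(
            BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=seed),
                n_estimators=n_trees,
                random_state=seed,
            ),
            standardize,
        )

    return factory


class _SklearnScorer:
    """Adapts a sklearn classifier to the fit/score_samples protocol."""

    def __init__(self, model, standardize: bool):
        self._model = model
        self._scaler = StandardScaler() if standardize else None

    def fit(self, X, y):
        if self._scaler is not None:
            X = self._scaler.fit_transform(X)
        self._model.fit(X, y)
        return self

    def score_samples(self, X):
        if self._scaler is not None:
            X = self._scaler.transform(X)
        proba = self._model.predict_proba(X)
        pos_col = list(self._model.classes_).index(1)
        return proba[:, pos_col]


_CLASSIFIERS = ("KNN", "BDT")


def _grid_for(classifier: str, cfg: BenchmarkConfig) -> tuple[int, ...]:
    return cfg.knn_grid if classifier == "KNN" else cfg.bdt_grid


def _factory_for(classifier: str, param: int, cfg: BenchmarkConfig):
    if classifier == "KNN":
        return _knn_factory(param, cfg.standardize)
    return _bdt_factory(param, cfg.standardize)


def tune_and_compare(
    matrix: FeatureMatrix,
    motif_sets: Mapping[str, Sequence[str]],
    cfg: BenchmarkConfig | None = None,
) -> pd.DataFrame:
    """Tune each classifier's grid and evaluate every motif set.

    For each (motif set, classifier) pair, the grid parameter with the
    best mean GM on a tuning pass is selected, then evaluated over the
    full protocol.  Tuning and final evaluation use disjoint seed
    streams derived from ``cfg.split.seed``.

    Returns a DataFrame with one row per (motif set, classifier):
    best parameter and mean/sd of GM and PPV.
    """
    cfg = cfg or BenchmarkConfig()
    resolved = {
        name: resolve_motif_names(names, matrix.catalog)
        for name, names in motif_sets.items()
    }
    root = np.random.SeedSequence(cfg.split.seed)
    tune_seed, eval_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)
    )
    tuning_runs = cfg.tuning_runs or cfg.split.n_runs
    rows = []
    for set_name in sorted(resolved):
        subset = resolved[set_name]
        for classifier in _CLASSIFIERS:
            grid = _grid_for(classifier, cfg)
            best_param, best_gm = None, -np.inf
            for param in grid:
                proto = SplitProtocol(
                    train_fraction=cfg.split.train_fraction,
                    n_runs=tuning_runs,
                    stratified=cfg.split.stratified,
                    seed=tune_seed,
                )
                ev = evaluate_subset(
                    matrix, subset, proto,
                    model_factory=_factory_for(classifier, param, cfg),
                )
                if ev.mean["gm"] > best_gm:
                    best_gm, best_param = ev.mean["gm"], param
            final_proto = SplitProtocol(
                train_fraction=cfg.split.train_fraction,
                n_runs=cfg.split.n_runs,
                stratified=cfg.split.stratified,
                seed=eval_seed,
            )
            ev = evaluate_subset(
                matrix, subset, final_proto,
                model_factory=_factory_for(classifier, best_param, cfg),
            )
            rows.append(
                {
                    "motif_set": set_name,
                    "classifier": classifier,
                    "best_param": best_param,
                    "gm_mean": ev.mean["gm"],
                    "gm_sd": ev.sd["gm"],
                    "ppv_mean": ev.mean["ppv"],
                    "ppv_sd": ev.sd["ppv"],
                    "mcc_mean": ev.mean["mcc"],
                    "auroc_mean": ev.mean["auroc"],
                }
            )
    return pd.DataFrame(rows)


def vargha_delaney_A(x: Sequence[float], y: Sequence[float]) -> float:
    """Vargha–Delaney A: P(X > Y) + 0.5 P(X = Y) over all pairs.

    0.5 means stochastic equality; 1.0 means every x exceeds every y.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    greater = np.sum(x[:, None] > y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    return float((greater + 0.5 * ties) / (x.size * y.size))
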