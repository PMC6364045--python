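"""Classifier evaluation under the repeated random-split protocol.

The selection protocol trains an unregularized logistic regression on a
small random fraction of the data (20% by default — deliberately small,
to favor generalization) and tests on the rest, repeating over many
independent stratified splits (300 by default).  Each run yields a full
set of binary-classification metrics; a subset of features is
characterized by the mean metric values across runs.

Metrics: sensitivity, specificity, PPV (precision), GM (geometric mean
of sensitivity and specificity), MCC, AUROC (tie-aware trapezoidal) and
AUPRC (step-wise precision-recall integration).  MCC is defined as 0
when its denominator vanishes; PPV is reported as 0 (with a flag) when
no positive predictions are made.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .encoding import FeatureMatrix

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "gm", "mcc",
                "auroc", "auprc")

#: iteration cap and tolerance of the maximum-likelihood fit; on
#: (quasi-)separation the fit at the cap is returned with converged=False
MAX_ITER = 200
TOL = 1e-8


@dataclass(frozen=True)
class SplitProtocol:
    """Repeated random train/test split configuration.

    Defaults match the signature-selection protocol (20% training,
    300 runs, stratified).  Benchmarking uses 60% training, 100 runs.
    """

    train_fraction: float = 0.2
    n_runs: int = 300
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    ppv: float
    gm: float
    mcc: float
    auroc: float
    auprc: float
    ppv_undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class FittedLogistic:
    """Unregularized binomial maximum-likelihood fit."""

    coef: np.ndarray
    intercept: float
    converged: bool
    n_iter: int

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(class = 1) for each row."""
        return _sigmoid(self.decision(X))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(z, -500, 500)))


def fit_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER, tol: float = TOL
) -> FittedLogistic:
    """Fit an unregularized logistic regression by maximum likelihood.

    Newton / iteratively-reweighted-least-squares iterations with
    step-halving on likelihood decrease.  On (quasi-)separated data the
    likelihood has no finite maximizer; the fit at the iteration cap is
    returned with ``converged=False`` — its predicted probabilities
    saturate, which is what thresholded classification needs.

    Raises
    ------
    ValueError
        If the design is all-constant (no column varies) or a class is
        missing from ``y``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    if np.unique(y).size < 2:
        raise ValueError("need both classes to fit")
    if np.all(X == X[0, :], axis=0).all():
        raise ValueError("all-constant design matrix")
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])  # intercept-first design
    beta = np.zeros(p + 1)
    eta = A @ beta

    def negloglik(eta_: np.ndarray) -> float:
        # -sum[y*eta - log(1+exp(eta))], computed stably
        return float(np.sum(np.logaddexp(0.0, eta_) - y * eta_))

    nll = negloglik(eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _sigmoid(eta)
        grad = A.T @ (y - mu)
        if np.max(np.abs(grad)) < tol * n:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            eta_new = A @ beta_new
            nll_new = negloglik(eta_new)
            if nll_new <= nll + 1e-12:
                break
            scale *= 0.5
        if abs(nll - nll_new) < tol * n and np.max(np.abs(grad)) < 1e-4 * n:
            beta, eta, nll = beta_new, eta_new, nll_new
            converged = True
            break
        beta, eta, nll = beta_new, eta_new, nll_new
    if not converged:
        logger.debug(
            "logistic fit hit the iteration cap (%d); likely "
            "(quasi-)separated data", max_iter,
        )
    return FittedLogistic(
        coef=beta[1:].copy(),
        intercept=float(beta[0]),
        converged=converged,
        n_iter=it,
    )


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """All classification metrics from scores and binary labels.

    ``scores`` are probabilities (or any monotone score for the ranking
    metrics); hard predictions are ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores and labels length mismatch: {scores.shape} vs "
            f"{labels.shape}"
        )
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv_undefined = (tp + fp) == 0
    ppv = 0.0 if ppv_undefined else tp / (tp + fp)
    gm = math.sqrt(sens * spec)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    return MetricSet(
        sensitivity=sens, specificity=spec, ppv=ppv, gm=gm, mcc=mcc,
        auroc=auroc, auprc=auprc, ppv_undefined=ppv_undefined,
    )


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random class-stratified index split.

    Each class contributes round(train_fraction * n_c) samples to the
    training side, at least 1 and at most n_c - 1 so both sides keep
    both classes whenever a class has >= 2 members.
    """
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = max(1, min(idx.size - 1, n_train))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def random_split(
    n: int, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_train = max(1, min(n - 1, int(round(train_fraction * n))))
    return idx[:n_train], idx[n_train:]


def default_model_factory(rng: np.random.Generator):
    """Model factory for the selection protocol: plain logistic regression."""

    class _LR:
        def fit(self, X, y):
            self._fit = fit_logistic(X, y)
            return self

        def score_samples(self, X):
            return self._fit.predict_proba(X)

    return _LR()


@dataclass
class SubsetEvaluation:
    """Per-run metrics and their mean/sd summary for one feature subset."""

    per_run: list[MetricSet]
    mean: dict[str, float]
    sd: dict[str, float]
    n_runs: int
    n_skipped: int
    subset: np.ndarray


def summarize_runs(per_run: Sequence[MetricSet]) -> tuple[dict, dict]:
    arr = {m: np.array([getattr(r, m) for r in per_run]) for m in METRIC_NAMES}
    mean = {m: float(v.mean()) for m, v in arr.items()}
    sd = {m: float(v.std(ddof=1)) if v.size > 1 else 0.0
          for m, v in arr.items()}
    return mean, sd


def evaluate_subset(
    matrix: FeatureMatrix,
    subset: Sequence[int],
    protocol: SplitProtocol,
    model_factory: Callable[[np.random.Generator], object] | None = None,
    threshold: float = 0.5,
) -> SubsetEvaluation:
    """Evaluate one feature subset under repeated random splits.

    For each run a fresh split is drawn, a model is fit on the training
    side and metrics are computed on the test side.  Runs in which a
    split side loses a class, or the restricted design is constant, are
    skipped with a warning; more than 10% skipped runs is an error.

    Fully reproducible from ``protocol.seed``.
    """
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ValueError("feature subset must be non-empty")
    X = matrix.values[:, subset]
    y = matrix.labels
    if np.unique(y).size < 2:
        raise ValueError("degenerate labels: only one class present")
    factory = model_factory or default_model_factory
    children = np.random.SeedSequence(protocol.seed).spawn(protocol.n_runs)
    per_run: list[MetricSet] = []
    n_skipped = 0
    for child in children:
        rng = np.random.default_rng(child)
        if protocol.stratified:
            tr, te = stratified_split(y, protocol.train_fraction, rng)
        else:
            tr, te = random_split(y.size, protocol.train_fraction, rng)
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            n_skipped += 1
            continue
        try:
            model = factory(rng)
            model.fit(X[tr], y[tr])
            scores = model.score_samples(X[te])
        except ValueError:
            n_skipped += 1
            continue
        per_run.append(compute_metrics(scores, y[te], threshold=threshold))
    if n_skipped:
        logger.warning("skipped %d/%d runs", n_skipped, protocol.n_runs)
        if n_skipped > 0.1 * protocol.n_runs:
            raise RuntimeError(
                f"{n_skipped}/{protocol.n_runs} runs skipped; data too "
                "small or degenerate for this protocol"
            )
    mean, sd = summarize_runs(per_run)
    return SubsetEvaluation(
        per_run=per_run, mean=mean, sd=sd,
        n_runs=len(per_run), n_skipped=n_skipped, subset=subset,
    )
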