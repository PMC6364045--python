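import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from motifsig import (SplitProtocol, compute_metrics, evaluate_subset,
                      fit_logistic)
from motifsig.encoding import FeatureMatrix, default_catalog
from motifsig.evaluation import stratified_split


def brute_force_metrics(scores, labels, threshold=0.5):
    """Independent confusion-count and rank-based recomputation."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= threshold
        if pred and y == 1:
            tp += 1
        elif pred and y == 0:
            fp += 1
        elif not pred and y == 0:
            tn += 1
        else:
            fn += 1
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = 0.0 if tp + fp == 0 else tp / (tp + fp)
    gm = math.sqrt(sens * spec)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    # AUROC = P(score_pos > score_neg) + 0.5 P(tie), all pairs
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos_scores
               for n in neg_scores)
    auroc = wins / (len(pos_scores) * len(neg_scores))
    # AUPRC: step-wise precision-recall integration over distinct scores
    order = np.argsort(-scores, kind="stable")
    auprc, prev_recall = 0.0, 0.0
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    for t in thresholds:
        predicted = scores >= t
        tp_t = int(np.sum(predicted & (labels == 1)))
        prec = tp_t / predicted.sum()
        rec = tp_t / n_pos
        auprc += (rec - prev_recall) * prec
        prev_recall = rec
    return dict(sensitivity=sens, specificity=spec, ppv=ppv, gm=gm,
                mcc=mcc, auroc=auroc, auprc=auprc)


class TestComputeMetrics:
    def test_worked_confusion_example(self):
        # TP=8 TN=7 FP=2 FN=3
        labels = np.array([1] * 8 + [0] * 7 + [0] * 2 + [1] * 3)
        scores = np.array([0.9] * 8 + [0.1] * 7 + [0.9] * 2 + [0.1] * 3)
        m = compute_metrics(scores, labels)
        assert m.mcc == pytest.approx(0.5025, abs=1e-4)
        # GM = sqrt((8/11) * (7/9))
        assert m.gm == pytest.approx(0.7521, abs=1e-4)
        assert m.ppv == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(8 / 11)
        assert m.specificity == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        m = compute_metrics(scores, labels)
        for name in ("sensitivity", "specificity", "ppv", "gm", "mcc",
                     "auroc", "auprc"):
            assert getattr(m, name) == pytest.approx(1.0)

    def test_constant_scores_chance_auroc(self):
        labels = np.array([1, 0] * 10)
        m = compute_metrics(np.full(20, 0.7), labels)
        assert m.auroc == pytest.approx(0.5)

    def test_no_positive_predictions_flags_ppv(self):
        labels = np.array([1, 1, 0, 0])
        m = compute_metrics(np.array([0.1, 0.2, 0.3, 0.4]), labels)
        assert m.ppv == 0.0
        assert m.ppv_undefined

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics(np.zeros(3), np.array([0, 1]))

    @settings(max_examples=80, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(6, 40))
    def test_matches_brute_force_recomputation(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        # quantized scores induce ties, exercising tie-aware AUROC
        scores = rng.integers(0, 6, size=n) / 5.0
        m = compute_metrics(scores, labels)
        bf = brute_force_metrics(scores, labels)
        for name, val in bf.items():
            assert getattr(m, name) == pytest.approx(val, abs=1e-10), name

    def test_auroc_invariant_under_monotone_score_transform(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        a = compute_metrics(scores, labels).auroc
        b = compute_metrics(np.exp(4 * scores), labels, threshold=1.0).auroc
        assert a == pytest.approx(b)

    def test_mcc_symmetric_under_class_and_score_swap(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        m1 = compute_metrics(scores, labels).mcc
        m2 = compute_metrics(1.0 - scores, 1 - labels,
                             threshold=0.5000001).mcc
        assert m1 == pytest.approx(m2, abs=1e-6)


class TestFitLogistic:
    def test_sign_separates_separable_1d(self):
        X = np.array([[-2.0], [-1.0], [-0.5], [0.5], [1.0], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_logistic(X, y)
        assert ((fit.predict_proba(X) >= 0.5).astype(int) == y).all()

    def test_intercept_only_balanced_gives_half(self):
        X = np.zeros((10, 1))
        X[:, 0] = 1.0  # constant column plus varying? no: keep constant
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="all-constant"):
            fit_logistic(X, y)
        # with one genuinely uninformative varying column the balanced
        # fit still predicts ~0.5 everywhere at the optimum of an
        # antisymmetric design
        X2 = np.array([[-1.0], [1.0]] * 5)
        fit = fit_logistic(X2, y)
        assert fit.predict_proba(np.zeros((1, 1)))[0] == pytest.approx(
            0.5, abs=1e-6
        )

    def test_matches_independent_optimizer(self, rng):
        X = rng.normal(size=(60, 2))
        logits = 0.8 * X[:, 0] - 1.4 * X[:, 1] + 0.2
        y = (rng.random(60) < 1 / (1 + np.exp(-logits))).astype(int)
        fit = fit_logistic(X, y)

        def nll(b):
            eta = X @ b[1:] + b[0]
            return np.sum(np.logaddexp(0, eta) - y * eta)

        res = minimize(nll, np.zeros(3), method="BFGS")
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coef], res.x, atol=1e-4
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.random.rand(5, 2), np.ones(5))

    def test_separated_data_flagged_but_usable(self):
        X = np.r_[np.full((5, 1), -1.0), np.full((5, 1), 1.0)]
        y = np.array([0] * 5 + [1] * 5)
        fit = fit_logistic(X, y)
        p = fit.predict_proba(X)
        assert (p[:5] < 0.01).all() and (p[5:] > 0.99).all()


def planted_matrix(n, rng, separation=3.0, n_features=5):
    catalog = default_catalog()
    labels = np.array([1] * (n // 2) + [0] * (n // 2))
    values = np.zeros((n, len(catalog)))
    values[:, :n_features] = rng.normal(size=(n, n_features)) * 0.1
    values[:, 0] += labels * separation * 0.1
    # keep within [0, 1]
    values = (values - values.min()) / (values.max() - values.min() + 1e-9)
    return FeatureMatrix(
        row_ids=[f"r{i}" for i in range(n)],
        labels=labels,
        values=values,
        catalog=catalog,
    )


class TestEvaluateSubset:
    def test_same_seed_reproduces_summary(self, rng):
        mat = planted_matrix(60, rng)
        proto = SplitProtocol(train_fraction=0.3, n_runs=20, seed=5)
        a = evaluate_subset(mat, [0, 1], proto)
        b = evaluate_subset(mat, [0, 1], proto)
        assert a.mean == b.mean and a.sd == b.sd

    def test_strong_separation_gives_high_mcc(self, rng):
        mat = planted_matrix(200, rng, separation=8.0)
        proto = SplitProtocol(train_fraction=0.2, n_runs=30, seed=2)
        ev = evaluate_subset(mat, [0], proto)
        assert ev.mean["mcc"] > 0.95

    def test_permuted_labels_give_null_mcc(self, rng):
        mat = planted_matrix(200, rng, separation=8.0)
        perm = rng.permutation(200)
        mat_null = FeatureMatrix(
            row_ids=mat.row_ids, labels=mat.labels[perm],
            values=mat.values, catalog=mat.catalog,
        )
        proto = SplitProtocol(train_fraction=0.2, n_runs=50, seed=3)
        ev = evaluate_subset(mat_null, [0, 1, 2], proto)
        assert abs(ev.mean["mcc"]) < 0.1

    def test_empty_subset_rejected(self, rng):
        mat = planted_matrix(20, rng)
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_subset(mat, [], SplitProtocol(n_runs=2, seed=0))

    def test_stratified_split_preserves_both_classes(self, rng):
        labels = np.array([1] * 8 + [0] * 42)
        tr, te = stratified_split(labels, 0.2, rng)
        assert set(labels[tr]) == {0, 1}
        assert set(labels[te]) == {0, 1}
        assert len(tr) + len(te) == 50
        assert sorted(np.r_[tr, te].tolist()) == list(range(50))
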