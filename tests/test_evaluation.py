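"""Metrics: confusion matrix, precision/recall/F1, fall-vs-rest ROC/AUC."""

from __future__ import annotations

import numpy as np
import pytest

from posefall import (
    CLASS_VOCABULARY,
    ConfusionMatrix,
    confusion_matrix,
    fall_binary_roc,
    precision_recall_f1,
    run_benchmark,
)


def _brute_force_prf(counts: np.ndarray) -> dict:
    """Independent per-class tally, looping over all (true, pred) pairs."""
    K = counts.shape[0]
    precision, recall, f1 = [], [], []
    for k in range(K):
        tp = counts[k, k]
        fp = sum(counts[i, k] for i in range(K) if i != k)
        fn = sum(counts[k, j] for j in range(K) if j != k)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(f)
    return {"precision": precision, "recall": recall, "f1": f1}


def _brute_force_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Normalized Mann-Whitney U by exhaustive pair counting (ties count 1/2)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = [c for c in CLASS_VOCABULARY for _ in range(3)]
        cm = confusion_matrix(labels, labels)
        assert np.trace(cm.counts) == 21
        assert cm.counts.sum() == 21
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_fall_row_worked_cells(self):
        """26 true falls: 20 predicted falling, 6 predicted lie."""
        true = ["falling"] * 26
        pred = ["falling"] * 20 + ["lie"] * 6
        cm = confusion_matrix(true, pred)
        assert cm["falling", "falling"] == 20
        assert cm["falling", "lie"] == 6

    def test_totals_and_row_sums_on_random_labels(self):
        rng = np.random.default_rng(10)
        true = [CLASS_VOCABULARY[i] for i in rng.integers(7, size=1000)]
        pred = [CLASS_VOCABULARY[i] for i in rng.integers(7, size=1000)]
        cm = confusion_matrix(true, pred)
        assert cm.total == 1000
        for k, cls in enumerate(CLASS_VOCABULARY):
            assert cm.counts[k].sum() == true.count(cls)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="jumping"):
            confusion_matrix(["falling"], ["jumping"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["falling"], ["falling", "lie"])


class TestPrecisionRecallF1:
    def test_hand_computed_example(self):
        # one class with TP=8, FP=2, FN=8 inside a 2-class matrix
        counts = np.array([[8, 8], [2, 0]])
        cm = ConfusionMatrix(counts, ("a", "b"))
        m = precision_recall_f1(cm)
        assert m["precision"]["a"] == pytest.approx(0.8)
        assert m["recall"]["a"] == pytest.approx(0.5)
        assert m["f1"]["a"] == pytest.approx(2 * 0.8 * 0.5 / 1.3)

    def test_perfect_matrix_scores_one(self):
        cm = ConfusionMatrix(np.diag([3] * 7), CLASS_VOCABULARY)
        m = precision_recall_f1(cm)
        assert m["macro_f1"] == 1.0 and m["macro_precision"] == 1.0 and m["accuracy"] == 1.0

    def test_zero_division_convention(self):
        counts = np.array([[5, 0], [3, 0]])  # nothing predicted as class b
        m = precision_recall_f1(ConfusionMatrix(counts, ("a", "b")))
        assert m["precision"]["b"] == 0.0 and m["recall"]["b"] == 0.0 and m["f1"]["b"] == 0.0
        assert "b" in m["zero_division_classes"]

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            K = int(rng.integers(2, 8))
            counts = rng.integers(0, 30, size=(K, K))
            classes = tuple(f"c{i}" for i in range(K))
            got = precision_recall_f1(ConfusionMatrix(counts, classes))
            want = _brute_force_prf(counts)
            for k, cls in enumerate(classes):
                assert got["precision"][cls] == pytest.approx(want["precision"][k], abs=1e-12)
                assert got["recall"][cls] == pytest.approx(want["recall"][k], abs=1e-12)
                assert got["f1"][cls] == pytest.approx(want["f1"][k], abs=1e-12)
            assert got["macro_f1"] == pytest.approx(np.mean(want["f1"]), abs=1e-12)

    def test_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            counts = rng.integers(0, 20, size=(5, 5))
            counts[0, 0] += 1  # avoid an all-zero matrix
            cm = ConfusionMatrix(counts, tuple("abcde"))
            tp = np.diag(counts).sum()
            fn = counts.sum() - tp
            micro_recall = tp / (tp + fn)
            assert precision_recall_f1(cm)["accuracy"] == pytest.approx(micro_recall, abs=1e-12)


class TestFallROC:
    def test_perfect_separation(self):
        labels = ["falling"] * 5 + ["standing"] * 5
        scores = np.array([0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.3, 0.05, 0.15])
        _, auc = fall_binary_roc(labels, scores)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        labels = ["falling"] * 5 + ["standing"] * 5
        _, auc = fall_binary_roc(labels, np.full(10, 0.5))
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney_u(self):
        rng = np.random.default_rng(33)
        y = rng.integers(0, 2, size=500)
        y[:2] = [0, 1]
        scores = rng.choice(np.linspace(0, 1, 40), size=500)  # ties on purpose
        labels = ["falling" if v else "standing" for v in y]
        _, auc = fall_binary_roc(labels, scores)
        assert auc == pytest.approx(_brute_force_auc(y, scores), abs=1e-9)

    def test_score_reversal_flips_auc(self):
        rng = np.random.default_rng(44)
        y = np.array([1] * 20 + [0] * 30)
        scores = rng.random(50)
        labels = ["falling" if v else "lie" for v in y]
        _, auc = fall_binary_roc(labels, scores)
        _, flipped = fall_binary_roc(labels, 1 - scores)
        assert flipped == pytest.approx(1 - auc, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fall_binary_roc(["falling", "falling"], np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            fall_binary_roc(["standing", "lie"], np.array([0.5, 0.6]))


class TestBenchmark:
    def test_table_shape_and_determinism(self, tiny_features):
        t1 = run_benchmark(tiny_features, ["transformer1", "lstm1"], [0], max_epochs=3)
        assert len(t1) == 2
        assert set(t1["preset"]) == {"transformer1", "lstm1"}
        assert t1[["macro_f1", "macro_precision", "fall_auc"]].notna().all().all()
        t2 = run_benchmark(tiny_features, ["transformer1", "lstm1"], [0], max_epochs=3)
        assert t1.equals(t2)
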