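"""Evaluation: per-class precision/recall/F1, confusion matrix, fall-vs-rest ROC/AUC.

Per class k the tallies come from the confusion matrix ``cm`` (rows = true,
columns = predicted): TP = cm[k][k], FP = column sum − TP, FN = row sum − TP;
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 is their harmonic mean.
Empty denominators yield 0 (conservative convention, flagged in the report).
The ROC binarizes the problem to the fall class versus everything else and
sweeps a threshold over the predicted fall probability; AUC is trapezoidal
(equivalently, the normalized Mann-Whitney U statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_curve

from .preprocessing import FeatureMatrix
from .schema import CLASS_VOCABULARY, FALL_CLASS


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = true class, columns = predicted class
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.classes)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be K x K for K classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        true_label, pred_label = pair
        return int(self.counts[self.classes.index(true_label), self.classes.index(pred_label)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


@dataclass
class EvalReport:
    """Per-class and aggregate metrics plus the fall-vs-rest ROC."""

    confusion: ConfusionMatrix
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_f1: float
    accuracy: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    zero_division_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.confusion.classes),
            "confusion_matrix": self.confusion.counts.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "accuracy": self.accuracy,
            "roc_points": self.roc_points,
            "auc": self.auc,
            "zero_division_classes": self.zero_division_classes,
        }


def confusion_matrix(
    true_labels: list[str], predicted_labels: list[str], vocabulary: tuple[str, ...] = CLASS_VOCABULARY
) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    vocab = tuple(vocabulary)
    for lab in set(true_labels) | set(predicted_labels):
        if lab not in vocab:
            raise ValueError(f"unknown label {lab!r}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(vocab))
    return ConfusionMatrix(counts=counts, classes=vocab)


def precision_recall_f1(cm: ConfusionMatrix) -> dict:
    """Per-class precision/recall/F1 from the confusion matrix, plus macro
    (unweighted) and support-weighted aggregates."""
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / np.maximum(precision + recall, 1e-300), 0.0)
    support = counts.sum(axis=1)
    total = max(support.sum(), 1)
    zero_div = [c for c, p_den, r_den in zip(cm.classes, tp + fp, tp + fn) if p_den == 0 or r_den == 0]
    return {
        "precision": dict(zip(cm.classes, precision.tolist())),
        "recall": dict(zip(cm.classes, recall.tolist())),
        "f1": dict(zip(cm.classes, f1.tolist())),
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "weighted_f1": float((f1 * support).sum() / total),
        "accuracy": float(tp.sum() / total),
        "zero_division_classes": zero_div,
    }


def fall_binary_roc(
    true_labels: list[str], fall_probabilities: np.ndarray, fall_class: str = FALL_CLASS
) -> tuple[list[tuple[float, float]], float]:
    """One-vs-rest ROC for the fall class and its trapezoidal AUC.

    Thresholds sweep the distinct scores (equal scores grouped); requires at
    least one positive and one negative example.
    """
    scores = np.asarray(fall_probabilities, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("fall probabilities must lie in [0, 1]")
    y = np.array([1 if lab == fall_class else 0 for lab in true_labels])
    if y.all() or not y.any():
        raise ValueError("ROC needs at least one positive and one negative example")
    fpr, tpr, _ = roc_curve(y, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def one_vs_rest_roc(
    true_labels: list[str], probabilities: np.ndarray, vocabulary: tuple[str, ...] = CLASS_VOCABULARY
) -> dict[str, tuple[list[tuple[float, float]], float]]:
    """Secondary per-class one-vs-rest curves (the fall curve is the headline)."""
    out = {}
    for j, cls in enumerate(vocabulary):
        try:
            out[cls] = fall_binary_roc(true_labels, probabilities[:, j], fall_class=cls)
        except ValueError:
            continue
    return out


def evaluate_predictions(
    true_labels: list[str],
    probabilities: np.ndarray,
    vocabulary: tuple[str, ...] = CLASS_VOCABULARY,
) -> EvalReport:
    """Full report from per-clip probability rows: argmax predictions feed the
    confusion matrix and class metrics; the fall-class column feeds the ROC."""
    probabilities = np.asarray(probabilities, dtype=float)
    pred = [vocabulary[i] for i in probabilities.argmax(axis=1)]
    cm = confusion_matrix(true_labels, pred, vocabulary)
    metrics = precision_recall_f1(cm)
    roc_points: list[tuple[float, float]] = []
    auc_value = None
    if FALL_CLASS in vocabulary:
        try:
            roc_points, auc_value = fall_binary_roc(
                true_labels, probabilities[:, vocabulary.index(FALL_CLASS)]
            )
        except ValueError:
            pass
    return EvalReport(
        confusion=cm,
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        macro_precision=metrics["macro_precision"],
        macro_recall=metrics["macro_recall"],
        macro_f1=metrics["macro_f1"],
        weighted_f1=metrics["weighted_f1"],
        accuracy=metrics["accuracy"],
        roc_points=roc_points,
        auc=auc_value,
        zero_division_classes=metrics["zero_division_classes"],
    )


def run_benchmark(
    features: list[FeatureMatrix],
    presets: list[str],
    seeds: list[int],
    vocabulary: tuple[str, ...] = CLASS_VOCABULARY,
    max_epochs: int | None = None,
) -> pd.DataFrame:
    """Train and evaluate each preset for each seed on a stratified split.

    Returns one row per (preset, seed) with macro-F1, macro-precision,
    weighted-F1, accuracy and fall-vs-rest AUC on the held-out test split.
    Deterministic: rerunning with the same seeds reproduces the table.
    """
    from .nn.training import build_preset, predict, split_dataset, train
    from .preprocessing import apply_minmax, fit_minmax

    if not features:
        raise ValueError("no features to benchmark")
    T, D = features[0].values.shape
    rows = []
    for name in presets:
        for seed in seeds:
            model, cfg = build_preset(name, D, T, seed=seed, max_epochs=max_epochs)
            tr, va, te = split_dataset(features, cfg)
            norm = fit_minmax(tr)
            tr, va, te_n = ([apply_minmax(m, norm) for m in part] for part in (tr, va, te))
            model, history = train(model, tr, va, cfg, vocabulary)
            probs = predict(model, te_n)
            report = evaluate_predictions([m.label for m in te], probs, vocabulary)
            rows.append(
                {
                    "preset": name,
                    "seed": seed,
                    "epochs": len(history["train_loss"]),
                    "macro_f1": report.macro_f1,
                    "macro_precision": report.macro_precision,
                    "weighted_f1": report.weighted_f1,
                    "accuracy": report.accuracy,
                    "fall_auc": report.auc,
                }
            )
    return pd.DataFrame(rows)
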