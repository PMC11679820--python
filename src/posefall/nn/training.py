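"""Training loop, optimizers, data splitting and benchmark presets.

Training minimizes categorical cross-entropy plus an L2 penalty on the dense
kernels, with a per-epoch cosine-decayed learning rate and early stopping on
validation loss (best weights restored).  Everything is driven by a single
seed: weight init, batch shuffling and dropout masks, so a rerun with the
same config reproduces identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..preprocessing import FeatureMatrix
from ..schema import CLASS_VOCABULARY
from .autodiff import Tensor, log_softmax
from .models import (
    RecurrentConfig,
    SequenceClassifier,
    TransformerConfig,
    build_recurrent,
    build_transformer,
)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    optimizer: str = "adam"  # adam | sgd | adamw
    base_learning_rate: float = 1e-3
    lr_schedule: str = "cosine_decay"  # cosine_decay | constant
    batch_size: int = 32
    max_epochs: int = 100
    early_stopping_patience: int = 10
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0
    weight_decay: float = 1e-4  # AdamW only

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("cosine_decay", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.base_learning_rate <= 0:
            raise ValueError("base_learning_rate must be > 0")
        if any(f <= 0 for f in self.split_fractions) or abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.early_stopping_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    features: list[FeatureMatrix], cfg: TrainConfig
) -> tuple[list[FeatureMatrix], list[FeatureMatrix], list[FeatureMatrix]]:
    """Stratified, seeded train/val/test partition of prepared features.

    Per-class counts follow the split fractions with largest-remainder
    rounding, so balanced datasets split into exactly balanced partitions.
    The three parts are disjoint and exhaustive.
    """
    by_label: dict[str, list[int]] = {}
    for i, m in enumerate(features):
        by_label.setdefault(m.label, []).append(i)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51D]))
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        if len(idx) < len(cfg.split_fractions):
            raise ValueError(f"class {label!r} has {len(idx)} clips; need at least {len(cfg.split_fractions)}")
        idx = idx[rng.permutation(len(idx))]
        quotas = _largest_remainder(len(idx), cfg.split_fractions)
        start = 0
        for part, quota in zip(parts, quotas):
            part.extend(idx[start : start + quota].tolist())
            start += quota
    return tuple([features[i] for i in sorted(part)] for part in parts)  # type: ignore[return-value]


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    # guarantee at least one item per partition, then apportion the rest
    raw = [f * n for f in fractions]
    counts = [max(1, int(np.floor(r))) for r in raw]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    remainders = [r - c for r, c in zip(raw, counts)]
    order = np.argsort(remainders)[::-1]
    for i in range(n - sum(counts)):
        counts[order[i % len(counts)]] += 1
    return counts


def features_to_arrays(
    features: list[FeatureMatrix], vocabulary: tuple[str, ...] = CLASS_VOCABULARY
) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature matrices into (N, T, D) inputs and integer labels."""
    lookup = {label: i for i, label in enumerate(vocabulary)}
    X = np.stack([m.values for m in features])
    y = np.array([lookup[m.label] for m in features], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# learning-rate schedule and optimizers


def cosine_decay(base_lr: float, epoch: int, total_epochs: int, alpha: float = 0.0) -> float:
    """Cosine-annealed learning rate: ``base_lr`` at epoch 0, decaying to
    ``alpha * base_lr`` by ``total_epochs``."""
    t = min(max(epoch, 0), total_epochs) / max(total_epochs, 1)
    return base_lr * (alpha + (1 - alpha) * 0.5 * (1.0 + np.cos(np.pi * t)))


class _Optimizer:
    def step(self, params: list[Tensor], lr: float) -> None:
        raise NotImplementedError


class SGD(_Optimizer):
    def step(self, params, lr):
        for p in params:
            if p.grad is not None:
                p.data -= lr * p.grad


class Adam(_Optimizer):
    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in params:
            if p.grad is None:
                continue
            key = id(p)
            m = self.m.setdefault(key, np.zeros_like(p.data))
            v = self.v.setdefault(key, np.zeros_like(p.data))
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    def __init__(self, weight_decay: float = 1e-4, **kwargs):
        super().__init__(**kwargs)
        self.weight_decay = weight_decay

    def step(self, params, lr):
        for p in params:
            if p.grad is not None:
                p.data -= lr * self.weight_decay * p.data
        super().step(params, lr)


def _make_optimizer(cfg: TrainConfig) -> _Optimizer:
    if cfg.optimizer == "sgd":
        return SGD()
    if cfg.optimizer == "adam":
        return Adam()
    return AdamW(weight_decay=cfg.weight_decay)


# ---------------------------------------------------------------------------
# training


def _as_arrays(data, vocabulary) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        X, y = data
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    return features_to_arrays(data, vocabulary)


def _loss_and_correct(model: SequenceClassifier, X, y, training, rng) -> tuple[Tensor, int]:
    logits = model.forward(X, training=training, rng=rng)
    logp = log_softmax(logits, axis=-1)
    # NLL through the graph via a one-hot contraction
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(y)), y] = 1.0
    loss = -(logp * Tensor(onehot)).sum() * (1.0 / len(y))
    l2w = getattr(model.cfg, "l2_weight", 0.0)
    if l2w > 0:
        for W in model.l2_terms():
            loss = loss + l2w * (W * W).sum()
    correct = int((logits.data.argmax(axis=1) == y).sum())
    return loss, correct


def train(
    model: SequenceClassifier,
    train_data,
    val_data,
    cfg: TrainConfig,
    vocabulary: tuple[str, ...] = CLASS_VOCABULARY,
) -> tuple[SequenceClassifier, dict[str, list[float]]]:
    """Fit the classifier; returns the model (best weights) and history.

    ``train_data``/``val_data`` are either lists of :class:`FeatureMatrix`
    or ``(X, y)`` arrays.  Stops when validation loss fails to improve for
    ``early_stopping_patience`` consecutive epochs and restores the best
    weights.  Raises :class:`TrainingDivergedError` on non-finite loss.
    """
    Xtr, ytr = _as_arrays(train_data, vocabulary)
    Xva, yva = _as_arrays(val_data, vocabulary)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("train and validation sets must be non-empty")
    opt = _make_optimizer(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7EA1]))
    params = model.parameters()
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [], "learning_rate": [],
    }
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(cfg.max_epochs):
        lr = (
            cosine_decay(cfg.base_learning_rate, epoch, cfg.max_epochs)
            if cfg.lr_schedule == "cosine_decay"
            else cfg.base_learning_rate
        )
        order = rng.permutation(len(Xtr))
        total_loss, total_correct = 0.0, 0
        for start in range(0, len(Xtr), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            for p in params:
                p.grad = None
            loss, correct = _loss_and_correct(model, Xtr[batch], ytr[batch], True, rng)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(epoch + 1)
            loss.backward()
            opt.step(params, lr)
            total_loss += float(loss.data) * len(batch)
            total_correct += correct
        val_loss, val_correct = _evaluate_loss(model, Xva, yva)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch + 1)
        history["train_loss"].append(total_loss / len(Xtr))
        history["train_acc"].append(total_correct / len(Xtr))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_correct / len(Xva))
        history["learning_rate"].append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stopping_patience:
                break
    model.set_weights(best_weights)
    return model, history


def _evaluate_loss(model: SequenceClassifier, X, y) -> tuple[float, int]:
    logits = model.forward(X, training=False)
    logp = log_softmax(logits, axis=-1).data
    loss = float(-logp[np.arange(len(y)), y].mean())
    correct = int((logits.data.argmax(axis=1) == y).sum())
    return loss, correct


def predict(model: SequenceClassifier, features, vocabulary: tuple[str, ...] = CLASS_VOCABULARY) -> np.ndarray:
    """Per-clip class-probability rows for arrays or feature-matrix lists."""
    if isinstance(features, list) and features and isinstance(features[0], FeatureMatrix):
        X = np.stack([m.values for m in features])
    else:
        X = np.asarray(features, dtype=float)
    return model.predict_proba(X)


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class Preset:
    kind: str  # transformer | lstm | gru
    model_cfg: TransformerConfig | RecurrentConfig
    train_cfg: TrainConfig


def _presets() -> dict[str, Preset]:
    t = lambda **kw: TransformerConfig(**kw)
    r = lambda **kw: RecurrentConfig(**kw)
    tc = lambda **kw: TrainConfig(**kw)
    return {
        "transformer1": Preset("transformer", t(dropout_rate=0.1), tc(optimizer="adam", base_learning_rate=1e-3, batch_size=32)),
        "transformer2": Preset("transformer", t(dropout_rate=0.3), tc(optimizer="adam", base_learning_rate=1e-3, batch_size=32)),
        "transformer3": Preset("transformer", t(dropout_rate=0.4), tc(optimizer="adamw", base_learning_rate=1e-3, batch_size=64)),
        "lstm1": Preset("lstm", r(kind="lstm", units=64, dropout_rate=0.2), tc(optimizer="adam", base_learning_rate=0.01, batch_size=32)),
        "lstm2": Preset("lstm", r(kind="lstm", units=64, dropout_rate=0.3), tc(optimizer="sgd", base_learning_rate=0.01, batch_size=32)),
        "lstm3": Preset("lstm", r(kind="lstm", units=64, dropout_rate=0.4), tc(optimizer="adamw", base_learning_rate=0.01, batch_size=64)),
        "gru1": Preset("gru", r(kind="gru", units=64, dropout_rate=0.2), tc(optimizer="adam", base_learning_rate=0.01, batch_size=32)),
        "gru2": Preset("gru", r(kind="gru", units=64, dropout_rate=0.3), tc(optimizer="sgd", base_learning_rate=0.01, batch_size=32)),
        "gru3": Preset("gru", r(kind="gru", units=128, dropout_rate=0.4), tc(optimizer="adamw", base_learning_rate=0.01, batch_size=64)),
    }


PRESETS: dict[str, Preset] = _presets()


def build_preset(
    name: str, d_in: int, T: int, seed: int = 0, max_epochs: int | None = None
) -> tuple[SequenceClassifier, TrainConfig]:
    """Instantiate a named benchmark preset for the given input shape."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    preset = PRESETS[name]
    train_cfg = replace(preset.train_cfg, seed=seed)
    if max_epochs is not None:
        train_cfg = replace(
            train_cfg,
            max_epochs=max_epochs,
            early_stopping_patience=min(train_cfg.early_stopping_patience, max_epochs),
        )
    if preset.kind == "transformer":
        model = build_transformer(d_in, T, preset.model_cfg, seed=seed)
    else:
        model = build_recurrent(d_in, T, preset.model_cfg, seed=seed)
    return model, train_cfg
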