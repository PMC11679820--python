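"""Sequence classifiers: transformer encoder and LSTM/GRU baselines.

The transformer follows the compact encoder-classifier recipe for short
multivariate time series: a linear projection of the input channels plus
sinusoidal positional encoding, a stack of pre-norm attention blocks with a
1-D convolutional feed-forward, global average pooling over time, an MLP
head with ReLU/dropout/L2, and a softmax output over the seven posture
classes.  The recurrent baselines swap the attention stack for stacked
LSTM/GRU layers and classify from the final hidden state.

Named presets mirror a benchmark grid of optimizer / dropout / batch-size
combinations for three transformer and six recurrent configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..schema import CLASS_VOCABULARY
from .autodiff import Tensor, dropout, relu, softmax
from .layers import (
    Dense,
    GRULayer,
    LSTMLayer,
    Module,
    TransformerBlock,
    sinusoidal_encoding,
)


@dataclass
class TransformerConfig:
    num_blocks: int = 2
    num_heads: int = 4
    key_dim: int = 32
    model_dim: int = 64
    ff_conv_filters: int | None = None  # None -> 4 * model_dim
    ff_conv_kernel: int = 1
    dropout_rate: float = 0.1
    mlp_units: list[int] = field(default_factory=lambda: [128])
    l2_weight: float = 1e-4
    num_classes: int = len(CLASS_VOCABULARY)
    positional_encoding: str = "sinusoidal"  # sinusoidal | learned | none

    def __post_init__(self) -> None:
        for name in ("num_blocks", "num_heads", "key_dim", "model_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid TransformerConfig.{name}: must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("invalid TransformerConfig.dropout_rate: must be in [0, 1)")
        if self.l2_weight < 0:
            raise ValueError("invalid TransformerConfig.l2_weight: must be >= 0")
        if self.positional_encoding not in ("sinusoidal", "learned", "none"):
            raise ValueError(f"invalid TransformerConfig.positional_encoding: {self.positional_encoding!r}")


@dataclass
class RecurrentConfig:
    kind: str = "lstm"  # lstm | gru
    units: int = 64
    num_layers: int = 1
    dropout_rate: float = 0.2
    num_classes: int = len(CLASS_VOCABULARY)

    def __post_init__(self) -> None:
        if self.kind not in ("lstm", "gru"):
            raise ValueError(f"invalid RecurrentConfig.kind: {self.kind!r}")
        if self.units < 1:
            raise ValueError("invalid RecurrentConfig.units: must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("invalid RecurrentConfig.dropout_rate: must be in [0, 1)")


class SequenceClassifier(Module):
    """Common surface: forward to logits, predict to probabilities."""

    d_in: int
    T: int
    num_classes: int

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode class probabilities, rows summing to 1."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.T or x.shape[2] != self.d_in:
            raise ValueError(f"expected input of shape (batch, {self.T}, {self.d_in}), got {x.shape}")
        logits = self.forward(x, training=False)
        return softmax(logits, axis=-1).data


class TransformerClassifier(SequenceClassifier):
    def __init__(self, d_in: int, T: int, cfg: TransformerConfig, seed: int = 0):
        self.d_in, self.T, self.num_classes = d_in, T, cfg.num_classes
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7F01]))
        d_model = cfg.model_dim
        ff_filters = cfg.ff_conv_filters or 4 * d_model
        self.input_proj = Dense(d_in, d_model, rng)
        if cfg.positional_encoding == "sinusoidal":
            self._posenc = Tensor(sinusoidal_encoding(T, d_model))
        elif cfg.positional_encoding == "learned":
            self._posenc = Tensor(rng.normal(0, 0.02, size=(T, d_model)), requires_grad=True)
        else:
            self._posenc = None
        self.blocks = [
            TransformerBlock(d_model, cfg.num_heads, cfg.key_dim, ff_filters, cfg.ff_conv_kernel, cfg.dropout_rate, rng)
            for _ in range(cfg.num_blocks)
        ]
        self.mlp = [Dense(d_model if i == 0 else cfg.mlp_units[i - 1], u, rng, regularized=True)
                    for i, u in enumerate(cfg.mlp_units)]
        last = cfg.mlp_units[-1] if cfg.mlp_units else d_model
        self.head = Dense(last, cfg.num_classes, rng, regularized=True)

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        h = self.input_proj(Tensor(np.asarray(x, dtype=float)))
        if self._posenc is not None:
            h = h + self._posenc
        for block in self.blocks:
            h = block(h, training, rng)
        h = h.mean(axis=1)  # global average pooling over time
        for dense in self.mlp:
            h = dropout(relu(dense(h)), self.cfg.dropout_rate, rng, training)
        return self.head(h)


class RecurrentClassifier(SequenceClassifier):
    def __init__(self, d_in: int, T: int, cfg: RecurrentConfig, seed: int = 0):
        self.d_in, self.T, self.num_classes = d_in, T, cfg.num_classes
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7F02]))
        layer_cls = LSTMLayer if cfg.kind == "lstm" else GRULayer
        self.layers = [
            layer_cls(d_in if i == 0 else cfg.units, cfg.units, rng) for i in range(cfg.num_layers)
        ]
        self.head = Dense(cfg.units, cfg.num_classes, rng, regularized=True)

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        h: Tensor | np.ndarray = Tensor(np.asarray(x, dtype=float))
        for k, layer in enumerate(self.layers):
            outputs = layer(h)
            if k + 1 < len(self.layers):
                B = outputs[0].shape[0]
                seq = [o.reshape(B, 1, self.cfg.units) for o in outputs]
                stacked = seq[0]
                for o in seq[1:]:
                    stacked = _concat_time(stacked, o)
                h = dropout(stacked, self.cfg.dropout_rate, rng, training)
            else:
                final = dropout(outputs[-1], self.cfg.dropout_rate, rng, training)
        return self.head(final)


def _concat_time(a, b):
    """Concatenate two tensors along axis 1 via padding and addition."""
    Ta, Tb = a.shape[1], b.shape[1]
    return a.pad_axis(1, 0, Tb) + b.pad_axis(1, Ta, 0)


def build_transformer(d_in: int, T: int, cfg: TransformerConfig | None = None, seed: int = 0) -> TransformerClassifier:
    """Assemble the transformer sequence classifier for T x d_in inputs."""
    if T < 1 or d_in < 1:
        raise ValueError("T and d_in must be >= 1")
    return TransformerClassifier(d_in, T, cfg or TransformerConfig(), seed=seed)


def build_recurrent(d_in: int, T: int, cfg: RecurrentConfig | None = None, seed: int = 0) -> RecurrentClassifier:
    """Assemble an LSTM or GRU baseline classifier for T x d_in inputs."""
    if T < 1 or d_in < 1:
        raise ValueError("T and d_in must be >= 1")
    return RecurrentClassifier(d_in, T, cfg or RecurrentConfig(), seed=seed)
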