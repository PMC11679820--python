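"""Neural-network building blocks on top of the autodiff engine.

Modules are lightweight objects exposing ``parameters()`` (flat list of
trainable :class:`~posefall.nn.autodiff.Tensor`) and a functional
``__call__``.  Weight initialization is Glorot-uniform from a seeded
generator, so model construction is fully reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, dropout, layer_norm, relu, sigmoid, tanh


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def l2_terms(self) -> list[Tensor]:
        """Kernels subject to L2 regularization (dense layers opt in)."""
        terms: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                terms.extend(value.l2_terms())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        terms.extend(item.l2_terms())
        return terms

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} weight arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.data.shape} vs {w.shape}")
            p.data = np.asarray(w, dtype=float).copy()


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, regularized: bool = False):
        self.W = Tensor(glorot(rng, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.regularized = regularized

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def l2_terms(self) -> list[Tensor]:
        return [self.W] if self.regularized else []


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


def sinusoidal_encoding(T: int, d: int) -> np.ndarray:
    """Classic fixed sin/cos positional table, shape (T, d)."""
    position = np.arange(T)[:, None]
    idx = np.arange(d)[None, :]
    angle = position / np.power(10000.0, (2 * (idx // 2)) / d)
    enc = np.zeros((T, d))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``num_heads`` heads.

    Queries/keys/values are linear projections to ``num_heads * key_dim``;
    the concatenated head outputs are projected back to the model width.
    """

    def __init__(self, d_model: int, num_heads: int, key_dim: int, rng: np.random.Generator):
        self.num_heads = num_heads
        self.key_dim = key_dim
        inner = num_heads * key_dim
        self.Wq = Dense(d_model, inner, rng)
        self.Wk = Dense(d_model, inner, rng)
        self.Wv = Dense(d_model, inner, rng)
        self.Wo = Dense(inner, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import softmax

        B, T, _ = x.shape
        h, dk = self.num_heads, self.key_dim

        def split(t: Tensor) -> Tensor:  # (B, T, h*dk) -> (B, h, T, dk)
            return t.reshape(B, T, h, dk).transpose((0, 2, 1, 3))

        q, k, v = split(self.Wq(x)), split(self.Wk(x)), split(self.Wv(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dk))
        weights = softmax(scores, axis=-1)
        ctx = weights @ v  # (B, h, T, dk)
        merged = ctx.transpose((0, 2, 1, 3)).reshape(B, T, h * dk)
        return self.Wo(merged)


class Conv1D(Module):
    """Position-wise 1-D convolution over the time axis ('same' padding).

    Implemented as a sum of shifted dense maps; with kernel 1 it reduces to a
    per-frame dense layer, the common transformer feed-forward choice.
    """

    def __init__(self, d_in: int, filters: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        if kernel > 1 and kernel % 2 == 0:
            raise ValueError("kernel must be odd for 'same' padding")
        self.kernel = kernel
        self.taps = [Tensor(glorot(rng, (d_in, filters)), requires_grad=True) for _ in range(kernel)]
        self.b = Tensor(np.zeros(filters), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if self.kernel == 1:
            return x @ self.taps[0] + self.b
        half = self.kernel // 2
        padded = x.pad_axis(1, half, half)
        T = x.shape[1]
        out = None
        for j, tap in enumerate(self.taps):
            term = padded.slice_axis(1, j, j + T) @ tap
            out = term if out is None else out + term
        return out + self.b


class TransformerBlock(Module):
    """Pre-norm encoder block: LN -> MHA -> dropout -> residual, then
    LN -> Conv1D feed-forward (ReLU) -> projection back -> residual."""

    def __init__(
        self,
        d_model: int,
        num_heads: int,
        key_dim: int,
        ff_filters: int,
        ff_kernel: int,
        dropout_rate: float,
        rng: np.random.Generator,
    ):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, num_heads, key_dim, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Conv1D(d_model, ff_filters, ff_kernel, rng)
        self.ff2 = Conv1D(ff_filters, d_model, 1, rng)
        self.dropout_rate = dropout_rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        a = self.attn(self.ln1(x))
        x = x + dropout(a, self.dropout_rate, rng, training)
        f = self.ff2(relu(self.ff1(self.ln2(x))))
        return x + dropout(f, self.dropout_rate, rng, training)


class LSTMLayer(Module):
    """Standard LSTM over the time axis; returns the full hidden sequence."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.W = Tensor(glorot(rng, (d_in, 4 * units)), requires_grad=True)
        self.U = Tensor(glorot(rng, (units, 4 * units)), requires_grad=True)
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> list[Tensor]:
        B, T, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((B, u)))
        c = Tensor(np.zeros((B, u)))
        outputs = []
        for t in range(T):
            xt = x.slice_axis(1, t, t + 1).reshape(B, x.shape[2])
            gates = xt @ self.W + h @ self.U + self.b
            i = sigmoid(gates.slice_axis(1, 0, u))
            f = sigmoid(gates.slice_axis(1, u, 2 * u))
            g = tanh(gates.slice_axis(1, 2 * u, 3 * u))
            o = sigmoid(gates.slice_axis(1, 3 * u, 4 * u))
            c = f * c + i * g
            h = o * tanh(c)
            outputs.append(h)
        return outputs

    @staticmethod
    def parameter_count(d_in: int, units: int) -> int:
        return 4 * (d_in * units + units * units + units)


class GRULayer(Module):
    """Standard GRU (reset applied before the candidate's recurrent term)."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.W = Tensor(glorot(rng, (d_in, 3 * units)), requires_grad=True)
        self.U = Tensor(glorot(rng, (units, 3 * units)), requires_grad=True)
        self.b = Tensor(np.zeros(3 * units), requires_grad=True)

    def __call__(self, x: Tensor) -> list[Tensor]:
        B, T, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((B, u)))
        outputs = []
        for t in range(T):
            xt = x.slice_axis(1, t, t + 1).reshape(B, x.shape[2])
            xw = xt @ self.W
            hu = h @ self.U
            z = sigmoid(xw.slice_axis(1, 0, u) + hu.slice_axis(1, 0, u) + self.b.slice_axis(0, 0, u))
            r = sigmoid(xw.slice_axis(1, u, 2 * u) + hu.slice_axis(1, u, 2 * u) + self.b.slice_axis(0, u, 2 * u))
            n = tanh(
                xw.slice_axis(1, 2 * u, 3 * u)
                + r * hu.slice_axis(1, 2 * u, 3 * u)
                + self.b.slice_axis(0, 2 * u, 3 * u)
            )
            h = (1.0 - z) * n + z * h
            outputs.append(h)
        return outputs

    @staticmethod
    def parameter_count(d_in: int, units: int) -> int:
        return 3 * (d_in * units + units * units + units)
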