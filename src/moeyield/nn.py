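"""Neural-network building blocks (layers, attention, LSTM) on the AD engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import (Tensor, concatenate, gelu, relu, sigmoid, silu,
                       softmax, tanh)

__all__ = [
    "Module", "Linear", "Dropout", "LayerNorm", "MultiheadSelfAttention",
    "TransformerEncoderLayer", "TransformerEncoder", "LSTM",
    "sinusoidal_positional_encoding", "ACTIVATIONS",
]

ACTIVATIONS = {"gelu": gelu, "relu": relu, "silu": silu, "tanh": tanh,
               "sigmoid": sigmoid}


class Module:
    """Base class with parameter traversal and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.array(state[name], dtype=np.float64, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def seed_dropout(self, seed: int) -> None:
        """Give every dropout layer one shared, freshly seeded generator."""
        rng = np.random.default_rng(seed)
        for _, module in _walk(self):
            if isinstance(module, Dropout):
                module.rng = rng

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _walk(module: Module):
    yield "", module
    for child in module.children():
        yield from _walk(child)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)),
            requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(out_features,)),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode before seeding")
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import layer_norm
        return layer_norm(x, self.gamma, self.beta, self.eps)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention, no causal mask."""

    def __init__(self, d_model: int, n_heads: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(
                f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.head_dim = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, b: int, t: int) -> Tensor:
        return x.reshape(b, t, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        q = self._split(self.q_proj(x), b, t)
        k = self._split(self.k_proj(x), b, t)
        v = self._split(self.v_proj(x), b, t)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, self.d_model)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer with a GELU feed-forward block."""

    def __init__(self, d_model: int, n_heads: int, dim_feedforward: int,
                 dropout: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.ff1 = Linear(d_model, dim_feedforward, rng)
        self.ff2 = Linear(dim_feedforward, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ff2(gelu(self.ff1(x)))))
        return x


class TransformerEncoder(Module):
    def __init__(self, d_model: int, n_heads: int, n_layers: int,
                 dim_feedforward: int, dropout: float,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.layers = [
            TransformerEncoderLayer(d_model, n_heads, dim_feedforward,
                                    dropout, rng)
            for _ in range(n_layers)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class _LSTMCellParams(Module):
    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(hidden_size)
        self.w_ih = Tensor(rng.uniform(-bound, bound, (input_size, 4 * hidden_size)),
                           requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-bound, bound, (hidden_size, 4 * hidden_size)),
                           requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, (4 * hidden_size,)),
                           requires_grad=True)
        self.hidden_size = hidden_size

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        hs = self.hidden_size
        gates = x_t @ self.w_ih + h @ self.w_hh + self.bias
        i = sigmoid(gates[:, 0 * hs:1 * hs])
        f = sigmoid(gates[:, 1 * hs:2 * hs])
        g = tanh(gates[:, 2 * hs:3 * hs])
        o = sigmoid(gates[:, 3 * hs:4 * hs])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new


class LSTM(Module):
    """Multi-layer (optionally bidirectional) LSTM, batch-first."""

    def __init__(self, input_size: int, hidden_size: int, num_layers: int = 1,
                 bidirectional: bool = False, dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.n_dirs = 2 if bidirectional else 1
        self.cells = []
        for layer in range(num_layers):
            in_size = input_size if layer == 0 else hidden_size * self.n_dirs
            for _ in range(self.n_dirs):
                self.cells.append(_LSTMCellParams(in_size, hidden_size, rng))
        self.inter_dropout = Dropout(dropout)

    def _run_direction(self, cell: _LSTMCellParams, x: Tensor,
                       reverse: bool) -> tuple[list[Tensor], Tensor]:
        b, t, _ = x.shape
        h = Tensor(np.zeros((b, cell.hidden_size)))
        c = Tensor(np.zeros((b, cell.hidden_size)))
        order = range(t - 1, -1, -1) if reverse else range(t)
        outputs: list[Tensor | None] = [None] * t
        for step in order:
            h, c = cell.step(x[:, step, :], h, c)
            outputs[step] = h
        return outputs, h  # h is the final state in scan order

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (per-step outputs [b,t,H*dirs], final hidden [b,H*dirs])."""
        b, t, _ = x.shape
        final = None
        for layer in range(self.num_layers):
            dir_outputs = []
            finals = []
            for d in range(self.n_dirs):
                cell = self.cells[layer * self.n_dirs + d]
                outs, h_last = self._run_direction(cell, x, reverse=(d == 1))
                seq = concatenate(
                    [o.reshape(b, 1, cell.hidden_size) for o in outs], axis=1)
                dir_outputs.append(seq)
                finals.append(h_last)
            x = (concatenate(dir_outputs, axis=2)
                 if self.n_dirs == 2 else dir_outputs[0])
            final = concatenate(finals, axis=1) if self.n_dirs == 2 else finals[0]
            if layer < self.num_layers - 1:
                x = self.inter_dropout(x)
        return x, final


def sinusoidal_positional_encoding(t: int, d: int) -> np.ndarray:
    """Standard sin/cos positional encoding matrix of shape (t, d)."""
    pe = np.zeros((t, d))
    position = np.arange(t)[:, None].astype(np.float64)
    div = np.exp(np.arange(0, d, 2) * (-math.log(10000.0) / d))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div[: pe[:, 1::2].shape[1]])
    return pe
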