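"""Dynamic-gated mixture-of-experts sequence regressor and its variants.

The full model embeds a (t x 10) monthly feature matrix, runs parallel
Transformer-encoder and bidirectional-LSTM branches, concatenates them into
h in R^{b x t x 2d}, routes the temporal mean of h through a sparse Top-2
gated pool of five heterogeneous experts (each with a linear adapter back to
width d), and fuses expert output with the two branch final states through a
512 -> 256 -> 1 head.

Ablation variants drop or densify pieces of this pipeline; three plain
baselines (lstm, transformer, lstm_transformer) share the embedding and head
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, concatenate, gelu, softmax
from .errors import InvalidConfigError, InvalidInputError
from .nn import (ACTIVATIONS, Dropout, Linear, LSTM, Module,
                 TransformerEncoder, sinusoidal_positional_encoding)

VARIANTS = ("lstm", "transformer", "lstm_transformer", "stf_moe",
            "stf_no_moe", "stf_single_expert", "stf_moe_dense")


@dataclass(frozen=True)
class ModelConfig:
    d: int = 128
    n_enc_layers: int = 4
    n_heads: int = 8
    lstm_layers: int = 2
    n_experts: int = 5
    top_k: int = 2
    gate_hidden: int = 256
    fusion_dims: tuple[int, int] = (512, 256)
    input_features: int = 10
    max_seq_len: int = 10
    dim_feedforward: int | None = None  # defaults to 4*d
    dropout_embed: float = 0.1
    dropout_encoder: float = 0.1
    dropout_lstm: float = 0.2
    dropout_fusion: float = 0.1
    renormalize_top_k: bool = False

    def __post_init__(self):
        if self.d % self.n_heads != 0:
            raise InvalidConfigError(
                f"hidden dim {self.d} not divisible by {self.n_heads} heads")
        if self.d % 4 != 0:
            raise InvalidConfigError(
                f"hidden dim {self.d} must be divisible by 4")
        if self.top_k > self.n_experts:
            raise InvalidConfigError("top_k cannot exceed n_experts")

    @property
    def ff_dim(self) -> int:
        return self.dim_feedforward or 4 * self.d

    def scaled(self, d: int) -> "ModelConfig":
        return replace(self, d=d)


# ---------------------------------------------------------------------------
# Heterogeneous expert pool
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpertSpec:
    """Layer-by-layer description of one expert.

    Each layer is (in_dim, out_dim, activation-or-None, dropout rate); the
    last layer's out_dim is the expert's native output width.
    """

    expert_id: int
    layers: tuple[tuple[int, int, str | None, float], ...]

    @property
    def native_dim(self) -> int:
        return self.layers[-1][1]


def expert_specs(d: int) -> list[ExpertSpec]:
    """The five resolved expert architectures for hidden dimension d."""
    half = d // 2
    return [
        # two-layer GELU expert, dropout 0.2 / 0.1
        ExpertSpec(0, ((2 * d, d, "gelu", 0.2), (d, d, "gelu", 0.1))),
        # wide single-hidden-layer ReLU expert, dropout 0.3, linear output
        ExpertSpec(1, ((2 * d, 2 * d, "relu", 0.3), (2 * d, d, None, 0.0))),
        # narrow SiLU expert (native width d/2), dropout 0.1
        ExpertSpec(2, ((2 * d, half, "silu", 0.1), (half, half, "silu", 0.0))),
        # single-layer GELU expert
        ExpertSpec(3, ((2 * d, d, "gelu", 0.0),)),
        # three-layer ReLU expert with d/2 hidden widths, dropout 0.2 each
        ExpertSpec(4, ((2 * d, half, "relu", 0.2), (half, half, "relu", 0.2),
                       (half, d, None, 0.0))),
    ]


class Expert(Module):
    """One expert network; counts how many sample evaluations it performs."""

    def __init__(self, spec: ExpertSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.linears = [Linear(i, o, rng) for i, o, _, _ in spec.layers]
        self.dropouts = [Dropout(p) for _, _, _, p in spec.layers]
        self.call_count = 0
        self.sample_call_count = 0

    def forward(self, x: Tensor) -> Tensor:
        self.call_count += 1
        self.sample_call_count += x.shape[0]
        for (_, _, act, _), lin, drop in zip(self.spec.layers, self.linears,
                                             self.dropouts):
            x = lin(x)
            if act is not None:
                x = ACTIVATIONS[act](x)
            if drop.p > 0:
                x = drop(x)
        return x


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

@dataclass
class GateDecision:
    """Per-sample expert probabilities with the Top-k selection."""

    g: np.ndarray          # (b, n_experts) probabilities
    indices: np.ndarray    # (b, k) selected expert ids, descending by prob
    weights: np.ndarray    # (b, k) raw gate entries (not renormalized)
    k: int


def top_k_select(g: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices/weights of the k largest gate entries, lowest index on ties."""
    order = np.argsort(-g, axis=-1, kind="stable")
    indices = order[..., :k]
    weights = np.take_along_axis(g, indices, axis=-1)
    return indices, weights


class GateNetwork(Module):
    """Two-layer GELU gate: softmax(W2 GELU(W1 h_avg + b1) + b2)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(2 * config.d, config.gate_hidden, rng)
        self.fc2 = Linear(config.gate_hidden, config.n_experts, rng)
        self.k = config.top_k

    def forward(self, h: Tensor) -> tuple[Tensor, GateDecision]:
        """h is (b, t, 2d); returns the probability tensor and the decision."""
        if np.any(np.isnan(h.data)):
            raise InvalidInputError("NaN in gate input features")
        h_avg = h.mean(axis=1)
        g = softmax(self.fc2(gelu(self.fc1(h_avg))), axis=-1)
        indices, weights = top_k_select(g.data, self.k)
        return g, GateDecision(g.data.copy(), indices, weights, self.k)


# ---------------------------------------------------------------------------
# Mixture-of-experts block
# ---------------------------------------------------------------------------

class MoEBlock(Module):
    """Top-k sparse (or dense / single-expert) mixture over five experts."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 mode: str = "sparse"):
        super().__init__()
        if mode not in ("sparse", "dense", "single"):
            raise InvalidConfigError(f"unknown MoE mode: {mode}")
        self.config = config
        self.mode = mode
        self.gate = GateNetwork(config, rng)
        specs = expert_specs(config.d)
        self.experts = [Expert(spec, rng) for spec in specs]
        self.adapters = [Linear(spec.native_dim, config.d, rng)
                         for spec in specs]
        self.last_decision: GateDecision | None = None

    def reset_counters(self) -> None:
        for e in self.experts:
            e.call_count = 0
            e.sample_call_count = 0

    @property
    def sample_evaluations(self) -> int:
        return sum(e.sample_call_count for e in self.experts)

    def forward(self, h: Tensor) -> Tensor:
        g, decision = self.gate(h)
        self.last_decision = decision
        h_avg = h.mean(axis=1)
        b = h_avg.shape[0]
        if self.mode == "single":
            return self.adapters[0](self.experts[0](h_avg))
        if self.mode == "dense":
            out = None
            for e in range(self.config.n_experts):
                adapted = self.adapters[e](self.experts[e](h_avg))
                weighted = adapted * g[:, e].reshape(b, 1)
                out = weighted if out is None else out + weighted
            return out
        # sparse Top-k: evaluate only selected experts, scatter back
        from .autodiff import scatter_rows
        if self.config.renormalize_top_k:
            rows_all = np.arange(b)[:, None]
            topk_sum = g[rows_all, decision.indices].sum(axis=1)  # (b,)
        out = None
        for e in range(self.config.n_experts):
            rows, _ = np.nonzero(decision.indices == e)
            if rows.size == 0:
                continue
            sub = h_avg.take_rows(rows)
            adapted = self.adapters[e](self.experts[e](sub))
            w = g[rows, np.full(rows.size, e)]
            if self.config.renormalize_top_k:
                w = w / topk_sum.take_rows(rows)
            piece = scatter_rows(adapted * w.reshape(-1, 1), rows, b)
            out = piece if out is None else out + piece
        return out


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class SequenceRegressor(Module):
    """One of the seven model variants; forward maps (b, t, 10) -> (b,)."""

    def __init__(self, variant: str, config: ModelConfig, seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise InvalidConfigError(
                f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.variant = variant
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.d
        self.embed = Linear(config.input_features, d, rng)
        self.embed_dropout = Dropout(config.dropout_embed)
        self.pe = sinusoidal_positional_encoding(config.max_seq_len, d)

        self.use_transformer = variant != "lstm"
        self.use_lstm = variant != "transformer"
        moe_mode = {"stf_moe": "sparse", "stf_moe_dense": "dense",
                    "stf_single_expert": "single"}.get(variant)

        if self.use_transformer:
            self.encoder = TransformerEncoder(
                d, config.n_heads, config.n_enc_layers, config.ff_dim,
                config.dropout_encoder, rng)
        if self.use_lstm:
            if d % 2 != 0:
                raise InvalidConfigError("hidden dim must be even for biLSTM")
            self.lstm = LSTM(d, d // 2, num_layers=config.lstm_layers,
                             bidirectional=True, dropout=config.dropout_lstm,
                             rng=rng)
        self.moe = MoEBlock(config, rng, moe_mode) if moe_mode else None

        head_in = {"lstm": d, "transformer": d, "lstm_transformer": 2 * d,
                   "stf_no_moe": 2 * d}.get(variant, 3 * d)
        f1, f2 = config.fusion_dims
        self.head1 = Linear(head_in, f1, rng)
        self.head2 = Linear(f1, f2, rng)
        self.head3 = Linear(f2, 1, rng)
        self.head_drop1 = Dropout(config.dropout_fusion)
        self.head_drop2 = Dropout(config.dropout_fusion)
        self.seed_dropout(seed + 1)

    # -- pieces exposed for testing ------------------------------------------
    def embed_and_encode(self, x: Tensor) -> Tensor:
        """Linear embedding plus sinusoidal positional encoding."""
        b, t, f = x.shape
        if f != self.config.input_features:
            raise InvalidInputError(
                f"expected {self.config.input_features} features, got {f}")
        if t > self.config.max_seq_len:
            raise InvalidInputError(f"sequence length {t} exceeds maximum")
        h = self.embed(x) + Tensor(self.pe[:t])
        return self.embed_dropout(h)

    def branches(self, x: Tensor) -> dict[str, Tensor]:
        h_emb = self.embed_and_encode(x)
        out: dict[str, Tensor] = {"h_emb": h_emb}
        if self.use_transformer:
            h_t = self.encoder(h_emb)
            out["h_T"] = h_t
            out["final_T"] = h_t[:, -1, :]
        if self.use_lstm:
            h_l, final_l = self.lstm(h_emb)
            out["h_L"] = h_l
            out["final_L"] = final_l
        if self.use_transformer and self.use_lstm:
            out["h"] = concatenate([out["h_T"], out["h_L"]], axis=2)
        return out

    def fusion_head(self, z: Tensor) -> Tensor:
        z = self.head_drop1(gelu(self.head1(z)))
        z = self.head_drop2(gelu(self.head2(z)))
        return self.head3(z)

    def forward(self, x: Tensor) -> Tensor:
        states = self.branches(x)
        if self.variant == "lstm":
            z = states["final_L"]
        elif self.variant == "transformer":
            z = states["final_T"]
        elif self.variant in ("lstm_transformer", "stf_no_moe"):
            z = concatenate([states["final_T"], states["final_L"]], axis=1)
        else:
            o_moe = self.moe(states["h"])
            z = concatenate([o_moe, states["final_T"], states["final_L"]],
                            axis=1)
        b = x.shape[0]
        return self.fusion_head(z).reshape(b)


def build_variant(name: str, config: ModelConfig | None = None,
                  seed: int = 0) -> SequenceRegressor:
    """Construct a model variant by name with a deterministic seed."""
    return SequenceRegressor(name, config or ModelConfig(), seed=seed)
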