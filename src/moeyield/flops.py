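"""Analytic per-sample forward-pass FLOP counts for each model variant.

Convention: a dense m -> n layer costs 2*m*n multiply-accumulate FLOPs;
attention and LSTM are tallied from their constituent matrix products;
activations, softmax and layer norms are ignored.  The sparse mixture counts
k experts at the mean per-expert cost (routing is input dependent, so a
deterministic convention is required); the dense mixture counts all experts.
"""

from __future__ import annotations

from .model import ModelConfig, SequenceRegressor, VARIANTS, expert_specs
from .errors import InvalidConfigError

__all__ = ["dense_flops", "count_flops", "count_flops_variant"]


def dense_flops(m: int, n: int) -> int:
    return 2 * m * n


def _encoder_layer_flops(d: int, t: int, ff: int, n_heads: int) -> int:
    qkv_out = 4 * t * dense_flops(d, d)       # Q, K, V and output projections
    scores = 2 * t * t * d                    # Q K^T across all heads
    mix = 2 * t * t * d                       # attention-weighted V
    ffn = t * (dense_flops(d, ff) + dense_flops(ff, d))
    return qkv_out + scores + mix + ffn


def _lstm_flops(d: int, t: int, n_layers: int) -> int:
    hidden = d // 2
    total = 0
    for layer in range(n_layers):
        in_size = d if layer == 0 else hidden * 2
        per_step = dense_flops(in_size, 4 * hidden) + dense_flops(hidden, 4 * hidden)
        total += 2 * t * per_step             # two directions
    return total


def _expert_flops(config: ModelConfig) -> list[int]:
    costs = []
    for spec in expert_specs(config.d):
        cost = sum(dense_flops(i, o) for i, o, _, _ in spec.layers)
        cost += dense_flops(spec.native_dim, config.d)  # adapter
        costs.append(cost)
    return costs


def _gate_flops(config: ModelConfig) -> int:
    return (dense_flops(2 * config.d, config.gate_hidden)
            + dense_flops(config.gate_hidden, config.n_experts))


def count_flops_variant(variant: str, config: ModelConfig | None = None,
                        t: int = 10) -> int:
    config = config or ModelConfig()
    if variant not in VARIANTS:
        raise InvalidConfigError(f"unknown variant {variant!r}")
    d = config.d
    total = t * dense_flops(config.input_features, d)   # embedding
    if variant != "lstm":
        total += config.n_enc_layers * _encoder_layer_flops(
            d, t, config.ff_dim, config.n_heads)
    if variant != "transformer":
        total += _lstm_flops(d, t, config.lstm_layers)
    if variant in ("stf_moe", "stf_moe_dense", "stf_single_expert"):
        total += _gate_flops(config)
        costs = _expert_flops(config)
        if variant == "stf_moe_dense":
            total += sum(costs)
        elif variant == "stf_single_expert":
            total += costs[0]
        else:  # sparse Top-k at mean expert cost
            total += round(config.top_k * sum(costs) / len(costs))
    head_in = {"lstm": d, "transformer": d, "lstm_transformer": 2 * d,
               "stf_no_moe": 2 * d}.get(variant, 3 * d)
    f1, f2 = config.fusion_dims
    total += dense_flops(head_in, f1) + dense_flops(f1, f2) + dense_flops(f2, 1)
    return int(total)


def count_flops(model: SequenceRegressor, t: int = 10) -> int:
    return count_flops_variant(model.variant, model.config, t=t)
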