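import numpy as np
import pytest

from moeyield import nn
from moeyield.autodiff import Tensor
from moeyield.errors import InvalidConfigError, InvalidInputError
from moeyield.model import (GateNetwork, ModelConfig, MoEBlock,
                            SequenceRegressor, VARIANTS, build_variant,
                            expert_specs, top_k_select, Expert)


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig(d=8, n_enc_layers=1, n_heads=2, lstm_layers=1,
                       fusion_dims=(16, 8))


class TestConfig:
    def test_defaults_match_stated_architecture(self):
        c = ModelConfig()
        assert (c.d, c.n_enc_layers, c.n_heads) == (128, 4, 8)
        assert (c.lstm_layers, c.n_experts, c.top_k) == (2, 5, 2)
        assert c.gate_hidden == 256 and c.fusion_dims == (512, 256)

    def test_invalid_head_divisibility(self):
        with pytest.raises(InvalidConfigError):
            ModelConfig(d=100, n_heads=8)

    def test_top_k_bound(self):
        with pytest.raises(InvalidConfigError):
            ModelConfig(top_k=6)


class TestGate:
    def test_zero_weights_uniform(self, cfg):
        gate = GateNetwork(cfg, np.random.default_rng(0))
        gate.fc1.weight.data[:] = 0
        gate.fc1.bias.data[:] = 0
        gate.fc2.weight.data[:] = 0
        gate.fc2.bias.data[:] = 0
        g, decision = gate(Tensor(np.ones((3, 4, 2 * cfg.d))))
        np.testing.assert_allclose(g.data, 0.2, atol=1e-12)

    def test_probability_simplex_many_inputs(self, cfg, rng):
        gate = GateNetwork(cfg, rng)
        g, _ = gate(Tensor(rng.normal(size=(2000, 3, 2 * cfg.d))))
        np.testing.assert_allclose(g.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(g.data >= 0)

    def test_nan_input_raises(self, cfg, rng):
        gate = GateNetwork(cfg, rng)
        bad = np.ones((1, 2, 2 * cfg.d))
        bad[0, 0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            gate(Tensor(bad))

    def test_top_k_forced_selection_unnormalized(self):
        g = np.array([[0.5, 0.3, 0.1, 0.06, 0.04]])
        idx, w = top_k_select(g, 2)
        np.testing.assert_array_equal(idx, [[0, 1]])
        np.testing.assert_allclose(w, [[0.5, 0.3]])
        assert w.sum() != 1.0  # weights are raw gate entries

    def test_top_k_lowest_index_tie_break(self):
        g = np.array([[0.25, 0.25, 0.25, 0.125, 0.125]])
        idx, _ = top_k_select(g, 2)
        np.testing.assert_array_equal(idx, [[0, 1]])


class TestExperts:
    def test_five_specs_and_native_dims(self, cfg):
        specs = expert_specs(cfg.d)
        assert len(specs) == 5
        assert [s.native_dim for s in specs] == \
            [cfg.d, cfg.d, cfg.d // 2, cfg.d, cfg.d]
        assert all(s.layers[0][0] == 2 * cfg.d for s in specs)

    def test_single_layer_expert_is_projected_gelu(self, cfg, rng):
        spec = expert_specs(cfg.d)[3]
        expert = Expert(spec, rng)
        expert.eval()
        x = rng.normal(size=(4, 2 * cfg.d))
        out = expert(Tensor(x))
        from moeyield.autodiff import gelu
        ref = gelu(Tensor(x) @ expert.linears[0].weight
                   + expert.linears[0].bias)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-12)

    def test_eval_mode_deterministic(self, cfg, rng):
        for spec in expert_specs(cfg.d):
            expert = Expert(spec, rng)
            expert.eval()
            x = Tensor(rng.normal(size=(2, 2 * cfg.d)))
            np.testing.assert_array_equal(expert(x).data, expert(x).data)

    @pytest.mark.parametrize("expert_id", range(5))
    def test_forward_matches_layerwise_oracle(self, cfg, rng, expert_id):
        """Independent layer-by-layer re-evaluation in plain NumPy."""
        spec = expert_specs(cfg.d)[expert_id]
        expert = Expert(spec, rng)
        expert.eval()
        x = rng.normal(size=(3, 2 * cfg.d))
        ref = x.copy()
        from scipy.special import erf
        acts = {
            "gelu": lambda z: z * 0.5 * (1 + erf(z / np.sqrt(2))),
            "relu": lambda z: np.maximum(z, 0),
            "silu": lambda z: z / (1 + np.exp(-z)),
            None: lambda z: z,
        }
        for (_, _, act, _), lin in zip(spec.layers, expert.linears):
            ref = acts[act](ref @ lin.weight.data + lin.bias.data)
        np.testing.assert_allclose(expert(Tensor(x)).data, ref, atol=1e-10)


class TestMoE:
    def test_sample_call_count_is_exactly_k(self, cfg, rng):
        moe = MoEBlock(cfg, rng, mode="sparse")
        moe.eval()
        b = 17
        moe(Tensor(rng.normal(size=(b, 4, 2 * cfg.d))))
        assert moe.sample_evaluations == cfg.top_k * b

    def test_single_mode_calls_one_expert(self, cfg, rng):
        moe = MoEBlock(cfg, rng, mode="single")
        moe.eval()
        moe(Tensor(rng.normal(size=(5, 4, 2 * cfg.d))))
        assert moe.experts[0].sample_call_count == 5
        assert sum(e.sample_call_count for e in moe.experts[1:]) == 0

    def test_dense_mode_calls_all_experts(self, cfg, rng):
        moe = MoEBlock(cfg, rng, mode="dense")
        moe.eval()
        moe(Tensor(rng.normal(size=(5, 4, 2 * cfg.d))))
        assert all(e.sample_call_count == 5 for e in moe.experts)

    def test_sparse_equals_dense_oracle_with_zeroed_weights(self, cfg, rng):
        """Dense all-expert evaluation with non-Top-2 weights zeroed."""
        sparse = MoEBlock(cfg, rng, mode="sparse")
        sparse.eval()
        x = rng.normal(size=(25, 4, 2 * cfg.d))
        out = sparse(Tensor(x))
        decision = sparse.last_decision
        h_avg = x.mean(axis=1)
        ref = np.zeros((25, cfg.d))
        for i in range(25):
            for j in range(cfg.top_k):
                e = decision.indices[i, j]
                val = sparse.adapters[e](
                    sparse.experts[e](Tensor(h_avg[i:i + 1]))).data[0]
                ref[i] += decision.weights[i, j] * val
        np.testing.assert_allclose(out.data, ref, atol=1e-10)

    def test_weighted_fusion_linearity(self, cfg, rng):
        """If both selected experts emit the same adapted vector o with
        weights w1 and w2 the output is (w1 + w2) * o."""
        moe = MoEBlock(cfg, rng, mode="sparse")
        moe.eval()
        shared = rng.normal(size=cfg.d)
        for e, adapter in enumerate(moe.adapters):
            adapter.weight.data[:] = 0
            adapter.bias.data = shared.copy()
        x = rng.normal(size=(4, 3, 2 * cfg.d))
        out = moe(Tensor(x))
        w_sum = moe.last_decision.weights.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out.data, w_sum * shared, atol=1e-10)


class TestVariants:
    @pytest.mark.parametrize("name", VARIANTS)
    def test_all_variants_finite_on_fixture(self, name, cfg, fixture_dataset):
        model = build_variant(name, cfg, seed=0)
        model.eval()
        X = np.stack([s.x for s in fixture_dataset.samples[:6]])
        out = model(Tensor(X))
        assert out.shape == (6,)
        assert np.all(np.isfinite(out.data))

    def test_unknown_variant(self, cfg):
        with pytest.raises(InvalidConfigError):
            build_variant("mlp", cfg)

    def test_single_expert_variant_calls_one(self, cfg, rng):
        model = build_variant("stf_single_expert", cfg, seed=0)
        model.eval()
        model(Tensor(rng.normal(size=(7, 10, 10))))
        assert model.moe.experts[0].sample_call_count == 7
        assert sum(e.sample_call_count for e in model.moe.experts[1:]) == 0

    def test_dense_with_one_hot_gate_equals_single_expert_path(self, cfg, rng):
        """Force the gate to a one-hot distribution: the dense mixture must
        reduce to that expert's adapted output alone."""
        dense = build_variant("stf_moe_dense", cfg, seed=3)
        dense.eval()
        # saturate the gate towards expert 2
        dense.moe.gate.fc2.weight.data[:] = 0
        dense.moe.gate.fc2.bias.data = np.array([-50., -50., 50., -50., -50.])
        x = rng.normal(size=(3, 10, 10))
        states = dense.branches(Tensor(x))
        out = dense.moe(states["h"])
        h_avg = states["h"].data.mean(axis=1)
        ref = dense.moe.adapters[2](dense.moe.experts[2](Tensor(h_avg)))
        np.testing.assert_allclose(out.data, ref.data, atol=1e-8)

    def test_embed_zero_input_gives_positional_encoding(self, cfg):
        model = build_variant("stf_moe", cfg, seed=0)
        model.eval()
        model.embed.weight.data[:] = 0
        model.embed.bias.data[:] = 0
        h = model.embed_and_encode(Tensor(np.zeros((1, 10, 10))))
        np.testing.assert_allclose(h.data[0], model.pe, atol=1e-12)

    def test_fusion_head_zero_weights_gives_bias(self, cfg):
        model = build_variant("stf_moe", cfg, seed=0)
        model.eval()
        for lin in (model.head1, model.head2, model.head3):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        model.head3.bias.data[:] = 7.25
        z = Tensor(np.ones((4, 3 * cfg.d)))
        np.testing.assert_allclose(model.fusion_head(z).data, 7.25)

    def test_fusion_head_matches_hand_matrix_evaluation(self, rng):
        small = ModelConfig(d=4, n_enc_layers=1, n_heads=2, lstm_layers=1,
                            fusion_dims=(6, 5))
        model = build_variant("stf_moe", small, seed=1)
        model.eval()
        z = rng.normal(size=(2, 12))
        from scipy.special import erf
        g = lambda v: v * 0.5 * (1 + erf(v / np.sqrt(2)))
        ref = g(z @ model.head1.weight.data + model.head1.bias.data)
        ref = g(ref @ model.head2.weight.data + model.head2.bias.data)
        ref = ref @ model.head3.weight.data + model.head3.bias.data
        np.testing.assert_allclose(model.fusion_head(Tensor(z)).data, ref,
                                   atol=1e-10)

    def test_permutation_sensitivity(self, cfg, rng):
        model = build_variant("stf_moe", cfg, seed=0)
        model.eval()
        x = rng.normal(size=(1, 10, 10))
        shuffled = x[:, rng.permutation(10), :]
        assert not np.allclose(model(Tensor(x)).data,
                               model(Tensor(shuffled)).data)

    def test_eval_determinism_bitwise(self, cfg, rng):
        model = build_variant("stf_moe", cfg, seed=0)
        model.eval()
        x = Tensor(rng.normal(size=(3, 10, 10)))
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_wrong_feature_count_raises(self, cfg):
        model = build_variant("stf_moe", cfg, seed=0)
        model.eval()
        with pytest.raises(InvalidInputError):
            model(Tensor(np.zeros((1, 10, 9))))

    def test_truncated_sequences_accepted(self, cfg, rng):
        model = build_variant("stf_moe", cfg, seed=0)
        model.eval()
        for t in (1, 4, 7):
            out = model(Tensor(rng.normal(size=(2, t, 10))))
            assert np.all(np.isfinite(out.data))


def test_state_dict_roundtrip(cfg, rng):
    a = build_variant("stf_moe", cfg, seed=0)
    b = build_variant("stf_moe", cfg, seed=99)
    b.load_state_dict(a.state_dict())
    a.eval(), b.eval()
    x = Tensor(rng.normal(size=(2, 10, 10)))
    np.testing.assert_array_equal(a(x).data, b(x).data)
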