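import numpy as np
import pytest

from tcrbind import (AttentionParams, BimodalAttentionNetwork, ModelConfig,
                     TrainConfig, build_model, context_attention,
                     tokenize_protein)
from tcrbind.autograd import Adam


def attention_oracle(X1, X2, W1, W2, W3, v):
    """Literal dense-math recomputation of the context-attention formula."""
    u = np.tanh(X1 @ W1 + W3 @ (X2 @ W2)) @ v
    e = np.exp(u)
    return e / e.sum()


def random_attention_instance(rng, T, U, H, K, A):
    X1 = rng.standard_normal((T, H))
    X2 = rng.standard_normal((U, K))
    params = AttentionParams(W1=rng.standard_normal((H, A)),
                             W2=rng.standard_normal((K, A)),
                             W3=rng.standard_normal((T, U)),
                             v=rng.standard_normal(A))
    return X1, X2, params


class TestContextAttention:
    def test_matches_literal_oracle(self, rng):
        X1, X2, params = random_attention_instance(rng, 5, 7, 3, 4, 6)
        amap, filtered = context_attention(X1, X2, params)
        expected = attention_oracle(X1, X2, params.W1, params.W2, params.W3,
                                    params.v)
        assert np.max(np.abs(amap.alphas - expected)) < 1e-6
        assert np.allclose(filtered, expected @ X1)

    def test_zero_inputs_give_uniform_attention(self, rng):
        _, _, params = random_attention_instance(rng, 6, 4, 3, 2, 5)
        amap, _ = context_attention(np.zeros((6, 3)), np.zeros((4, 2)), params)
        assert np.allclose(amap.alphas, 1 / 6)

    def test_weights_positive_and_normalized(self, rng):
        for _ in range(5):
            X1, X2, params = random_attention_instance(rng, 8, 5, 4, 3, 6)
            amap, _ = context_attention(X1, X2, params)
            assert np.all(amap.alphas > 0)
            assert amap.alphas.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_names_offender(self, rng):
        X1, X2, params = random_attention_instance(rng, 5, 7, 3, 4, 6)
        params.W3 = params.W3[:, :-1]
        with pytest.raises(ValueError, match="W3"):
            context_attention(X1, X2, params)


class TestBuildModel:
    def test_base_config_has_four_channels_with_residual(self):
        cfg = ModelConfig.base(tcr_len=20, epitope_len=14)
        net = build_model(cfg, rng_seed=0)
        # 3 convolution channels per stream; channel 3 is the residual
        assert {n for n in net.params if n.startswith("tcr.conv")} == \
            {f"tcr.conv{i}.{p}" for i in range(3) for p in ("W", "b")}
        assert "tcr.att3.W1" in net.params  # residual channel still attends
        assert net.params["tcr.att3.W1"].shape[0] == 26  # raw embedding dim

    def test_base_dense_stack_sizes(self):
        net = build_model(ModelConfig.base(tcr_len=20, epitope_len=14), 0)
        assert net.params["dense0.W"].shape[1] == 368
        assert net.params["dense1.W"].shape == (368, 184)

    def test_pretrain_config_shapes(self):
        cfg = ModelConfig.pretrain(tcr_len=40, epitope_len=30)
        assert cfg.attention_dim == 256
        assert cfg.kernel_sizes_tcr == (3, 7, 13, 19)
        assert cfg.kernel_sizes_epitope == (3, 7, 9, 13)
        assert cfg.dense_sizes == (2048, 1024, 512)

    def test_same_seed_gives_identical_parameters(self, tiny_config):
        a = build_model(tiny_config, rng_seed=5)
        b = build_model(tiny_config, rng_seed=5)
        for name in a.params:
            assert np.array_equal(a.params[name].data, b.params[name].data)

    def test_parameter_count_is_config_function(self):
        # regression constant for the default reduced configuration
        net = build_model(ModelConfig.reduced(), rng_seed=0)
        assert net.parameter_count == 156993

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_sizes_tcr=(3, 5), kernel_sizes_epitope=(3,))
        with pytest.raises(ValueError):
            ModelConfig(attention_dim=0)


@pytest.fixture(scope="module")
def net_and_batch(tiny_config):
    net = build_model(tiny_config, rng_seed=1)
    seqs_t = ["CASSLGQAYEQY", "CASSIRSSYEQF", "CAWSVSDLAKNI"]
    seqs_e = ["GILGFVFT", "NLVPMVAT", "ELAGIGIL"]
    t = np.stack([tokenize_protein(s, 14).array for s in seqs_t])
    e = np.stack([tokenize_protein(s, 10).array for s in seqs_e])
    return net, t, e


class TestForward:

    def test_probability_strictly_in_unit_interval(self, net_and_batch):
        net, t, e = net_and_batch
        p = net.predict_proba(t, e)
        assert np.all((p > 0) & (p < 1))

    def test_eval_mode_deterministic(self, net_and_batch):
        net, t, e = net_and_batch
        assert np.array_equal(net.predict_proba(t, e), net.predict_proba(t, e))

    def test_batch_order_invariance(self, net_and_batch):
        net, t, e = net_and_batch
        p = net.predict_proba(t, e)
        perm = [2, 0, 1]
        q = net.predict_proba(t[perm], e[perm])
        assert np.max(np.abs(q - p[perm])) < 1e-6

    def test_attention_rows_sum_to_one_per_channel(self, net_and_batch):
        net, t, e = net_and_batch
        out = net.forward(t, e, return_attention=True)
        for stream in ("tcr", "epi"):
            for alpha in out["attention"][stream]:
                assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_length_mismatch_raises(self, net_and_batch):
        net, t, e = net_and_batch
        with pytest.raises(ValueError, match="length"):
            net.forward(t[:, :-1], e)

    def test_checkpoint_round_trip(self, net_and_batch, tmp_path):
        net, t, e = net_and_batch
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = BimodalAttentionNetwork.load(path)
        assert np.array_equal(loaded.predict_proba(t, e),
                              net.predict_proba(t, e))


class TestTrainableScopes:
    def _one_step(self, net, t, e, labels):
        opt = Adam(net.parameters(), lr=1e-2)
        loss = net.loss(t, e, labels, training=True,
                        dropout_rng=np.random.default_rng(0))
        loss.backward()
        opt.step()

    def test_semifrozen_keeps_epitope_stream_bit_identical(self, tiny_config):
        net = build_model(tiny_config, rng_seed=3)
        net.set_trainable_scopes("semifrozen")
        before = {n: p.data.copy() for n, p in net.params.items()}
        rng = np.random.default_rng(4)
        t = rng.integers(0, 20, size=(8, tiny_config.tcr_len))
        e = rng.integers(0, 20, size=(8, tiny_config.epitope_len))
        self._one_step(net, t, e, rng.integers(0, 2, size=8))
        changed = {n for n, p in net.params.items()
                   if not np.array_equal(p.data, before[n])}
        assert not any(n.startswith("epi.") for n in changed)
        assert any(n.startswith("tcr.") for n in changed)
        assert any(n.startswith(("dense", "out")) for n in changed)

    def test_all_mode_gradients_reach_every_trainable_parameter(self, tiny_config):
        net = build_model(tiny_config, rng_seed=5)
        net.set_trainable_scopes("all")
        rng = np.random.default_rng(6)
        t = rng.integers(2, 20, size=(16, tiny_config.tcr_len))
        e = rng.integers(2, 20, size=(16, tiny_config.epitope_len))
        loss = net.loss(t, e, rng.integers(0, 2, size=16), training=False)
        loss.backward()
        for name, p in net.params.items():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_toggling_scopes_preserves_values(self, tiny_config):
        net = build_model(tiny_config, rng_seed=7)
        snapshot = {n: p.data.copy() for n, p in net.params.items()}
        net.set_trainable_scopes("semifrozen")
        net.set_trainable_scopes("all")
        for n, p in net.params.items():
            assert np.array_equal(p.data, snapshot[n])
        assert all(p.trainable for n, p in net.params.items()
                   if n != "tcr.embedding" or net.embedding_specs["tcr"].trainable)

    def test_unknown_mode_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            build_model(tiny_config, 0).set_trainable_scopes("half")
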