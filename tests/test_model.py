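"""Network layers vs. loop oracles, shape contracts, gradient flow."""

import dataclasses

import numpy as np
import pytest

import oracles
from dstan import DstanModel, ModelConfig, NormalizedAdjacency
from dstan._autodiff import Tensor, backward
from dstan.model import (apply_attention, compress_head, fuse, graph_conv,
                         node_attention, pooled_length, temporal_conv)


def _adj(n, rng=None):
    """A valid random (or identity) normalized adjacency for tests."""
    if rng is None:
        return NormalizedAdjacency(values=np.eye(n))
    W = np.abs(rng.standard_normal((n, n)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    A = np.eye(n) + W
    d = 1 / np.sqrt(A.sum(axis=1))
    return NormalizedAdjacency(values=(A * d[:, None]) * d[None, :])


class TestTemporalConv:
    def test_study_scale_output_shape(self, rng):
        f = Tensor(rng.standard_normal((1, 90, 80, 1)))
        W = Tensor(rng.standard_normal((5, 8)))
        out = temporal_conv(f, W, Tensor(np.zeros(8)), w=5, s=2)
        assert out.shape == (1, 90, 38, 8)
        assert pooled_length(80, 5, 2) == 38

    def test_constant_input_sums_kernel(self):
        f = Tensor(np.full((1, 3, 10, 1), 2.0))
        W = Tensor(np.full((4, 1), 0.5))  # kernel sums to 2.0
        out = temporal_conv(f, W, Tensor(np.zeros(1)), w=4, s=1)
        assert np.allclose(out.data, 2.0 * 2.0)

    def test_matches_loop_oracle(self, rng):
        f = rng.standard_normal((1, 4, 10, 2))
        W = rng.standard_normal((3 * 2, 5))
        b = rng.standard_normal(5)
        fast = temporal_conv(Tensor(f), Tensor(W), Tensor(b), w=3, s=2)
        slow = oracles.temporal_conv_loop(f, W, b, w=3, s=2)
        assert np.allclose(fast.data, slow, atol=1e-6)

    def test_short_series_raises_with_sizes(self, rng):
        f = Tensor(rng.standard_normal((1, 2, 3, 1)))
        with pytest.raises(ValueError, match="3.*5"):
            temporal_conv(f, Tensor(np.zeros((5, 1))), Tensor(np.zeros(1)),
                          w=5, s=1)


class TestGraphConv:
    def test_identity_adjacency_is_channel_mixing(self, rng):
        f = rng.standard_normal((2, 4, 6, 3))
        W = rng.standard_normal((3, 5))
        b = rng.standard_normal(5)
        out = graph_conv(Tensor(f), _adj(4), Tensor(W), Tensor(b))
        assert np.allclose(out.data, np.maximum(f @ W + b, 0.0))

    def test_zero_weights_zero_output(self, rng):
        f = rng.standard_normal((1, 4, 6, 3))
        out = graph_conv(Tensor(f), _adj(4, rng), Tensor(np.zeros((3, 2))),
                         Tensor(np.zeros(2)))
        assert np.all(out.data == 0.0)

    def test_matches_loop_oracle(self, rng):
        f = rng.standard_normal((2, 5, 7, 3))
        S = _adj(5, rng)
        W = rng.standard_normal((3, 4))
        b = rng.standard_normal(4)
        fast = graph_conv(Tensor(f), S, Tensor(W), Tensor(b))
        slow = oracles.graph_conv_loop(f, S.values, W, b)
        assert np.allclose(fast.data, slow, atol=1e-6)

    def test_node_mismatch_raises(self, rng):
        f = Tensor(rng.standard_normal((1, 4, 6, 3)))
        with pytest.raises(ValueError, match="node dimension"):
            graph_conv(f, _adj(5), Tensor(np.zeros((3, 2))),
                       Tensor(np.zeros(2)))


class TestNodeAttention:
    def test_bottleneck_width_from_ratio(self):
        cfg = ModelConfig(n_nodes=90, t_in=80, attention_ratio=16)
        assert cfg.bottleneck_width == 5

    def test_identical_node_rows_give_uniform_attention(self, rng):
        row = rng.standard_normal((1, 1, 6, 3))
        fhat = np.repeat(row, 5, axis=1)  # all 5 nodes identical
        Z = node_attention(Tensor(fhat), Tensor(rng.standard_normal((6, 3))),
                           Tensor(rng.standard_normal(3)),
                           Tensor(rng.standard_normal((5, 2))),
                           Tensor(rng.standard_normal(2)),
                           Tensor(rng.standard_normal((2, 5))),
                           Tensor(rng.standard_normal(5)))
        # equal per-node summaries enter the FC maps; the maps may still
        # differentiate nodes, but the channel-average input is constant
        M = np.maximum((fhat * 0 + fhat).sum(2), 0)
        assert np.allclose(M.mean(-1), M.mean(-1)[:, :1])
        assert Z.shape == (1, 5)

    def test_zero_input_zero_bias_gives_half(self):
        fhat = Tensor(np.zeros((2, 6, 4, 3)))
        Z = node_attention(fhat, Tensor(np.zeros((4, 3))),
                           Tensor(np.zeros(3)), Tensor(np.zeros((6, 2))),
                           Tensor(np.zeros(2)), Tensor(np.zeros((2, 6))),
                           Tensor(np.zeros(6)))
        assert np.allclose(Z.data, 0.5)

    def test_matches_loop_oracle(self, rng):
        fhat = rng.standard_normal((2, 5, 4, 3))
        args = (rng.standard_normal((4, 3)), rng.standard_normal(3),
                rng.standard_normal((5, 2)), rng.standard_normal(2),
                rng.standard_normal((2, 5)), rng.standard_normal(5))
        fast = node_attention(Tensor(fhat), *map(Tensor, args))
        slow = oracles.node_attention_loop(fhat, *args)
        assert np.allclose(fast.data, slow, atol=1e-6)

    def test_tiny_ratio_rejected(self):
        with pytest.raises(ValueError, match="attention_ratio"):
            ModelConfig(n_nodes=10, t_in=80, attention_ratio=16)


class TestApplyAttentionAndFuse:
    def test_unit_attention_is_identity(self, rng):
        fhat = rng.standard_normal((2, 4, 5, 3))
        out = apply_attention(Tensor(np.ones((2, 4))), Tensor(fhat))
        assert np.array_equal(out.data, fhat)

    def test_zero_attention_silences(self, rng):
        fhat = rng.standard_normal((2, 4, 5, 3))
        out = apply_attention(Tensor(np.zeros((2, 4))), Tensor(fhat))
        assert np.all(out.data == 0.0)

    def test_matches_loop_oracle(self, rng):
        Z = rng.uniform(0.001, 0.999, size=(2, 4))
        fhat = rng.standard_normal((2, 4, 5, 3))
        fast = apply_attention(Tensor(Z), Tensor(fhat))
        assert np.allclose(fast.data,
                           oracles.apply_attention_loop(Z, fhat), atol=1e-12)

    def test_fuse_is_commutative_sum(self, rng):
        a, b = rng.standard_normal((2, 3, 4, 2)), \
            rng.standard_normal((2, 3, 4, 2))
        assert np.array_equal(fuse(Tensor(a), Tensor(b)).data, a + b)
        assert np.array_equal(fuse(Tensor(b), Tensor(a)).data, a + b)

    def test_fuse_rejects_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fuse(Tensor(np.zeros((1, 2, 3, 4))),
                 Tensor(np.zeros((1, 2, 3, 5))))


class TestCompressHead:
    def test_uniform_kernels_give_global_means(self, rng):
        hL = rng.standard_normal((2, 4, 6, 3))
        u = np.full((4, 6, 3), 1.0 / 24)  # averaging kernel per channel
        fcW = np.zeros((3, 2))
        fcW[0, 0] = fcW[1, 1] = 1.0  # identity-like on 2 of 3 channels
        scores = compress_head(Tensor(hL), Tensor(u), Tensor(fcW),
                               Tensor(np.zeros(2)))
        assert np.allclose(scores.data[:, 0], hL[..., 0].mean(axis=(1, 2)))
        assert np.allclose(scores.data[:, 1], hL[..., 1].mean(axis=(1, 2)))

    def test_channel_count_before_fc(self):
        model = DstanModel(ModelConfig())
        assert model.params["head_u"].data.shape[2] == 32
        assert model.params["head_W"].data.shape == (32, 2)

    def test_matches_flatten_dot_oracle(self, rng):
        hL = rng.standard_normal((3, 4, 5, 2))
        u = rng.standard_normal((4, 5, 2))
        fcW = rng.standard_normal((2, 2))
        fcb = rng.standard_normal(2)
        fast = compress_head(Tensor(hL), Tensor(u), Tensor(fcW),
                             Tensor(fcb))
        slow = oracles.compress_head_loop(hL, u, fcW, fcb)
        assert np.allclose(fast.data, slow, atol=1e-6)


class TestForward:
    def test_study_settings_run_and_classify(self, rng):
        cfg = ModelConfig()  # n=90, T=80, channels (8,16,32), r=16
        model = DstanModel(cfg)
        X = rng.standard_normal((2, 80, 90))
        scores, zmaps = model.forward(X, _adj(90, rng))
        assert scores.shape == (2, 2)
        assert len(zmaps) == 3
        assert all(z.shape == (2, 90) for z in zmaps)

    def test_attention_strictly_inside_unit_interval(self, rng):
        model = DstanModel(ModelConfig(n_nodes=8, t_in=20,
                                       channels=(2, 3), w=3, s=2,
                                       attention_ratio=2, seed=1))
        _, zmaps = model.forward(rng.standard_normal((4, 20, 8)),
                                 _adj(8, rng))
        for Z in zmaps:
            assert np.all(Z.data > 0.0) and np.all(Z.data < 1.0)

    def test_no_cross_subject_coupling(self, rng):
        model = DstanModel(ModelConfig(n_nodes=6, t_in=16, channels=(2, 2),
                                       w=3, s=2, attention_ratio=2, seed=0))
        S = _adj(6, rng)
        X = rng.standard_normal((8, 16, 6))
        batch_scores, _ = model.forward(X, S)
        single_scores, _ = model.forward(X[3], S)
        assert np.allclose(batch_scores.data[3], single_scores.data[0],
                           atol=1e-12)

    def test_forward_is_deterministic(self, rng):
        model = DstanModel(ModelConfig(n_nodes=6, t_in=16, channels=(2,),
                                       w=3, s=2, attention_ratio=2, seed=5))
        S = _adj(6, rng)
        X = rng.standard_normal((3, 16, 6))
        s1, _ = model.forward(X, S)
        s2, _ = model.forward(X, S)
        assert np.array_equal(s1.data, s2.data)

    @pytest.mark.parametrize("use_attention,fuse_raw", [
        (True, False), (True, True), (False, False)])
    def test_full_forward_matches_loop_oracle(self, rng, use_attention,
                                              fuse_raw):
        cfg = ModelConfig(n_nodes=4, t_in=10, channels=(2, 3), w=3, s=1,
                          attention_ratio=2, seed=2,
                          use_attention=use_attention, fuse_raw=fuse_raw)
        model = DstanModel(cfg)
        S = _adj(4, rng)
        X = rng.standard_normal((3, 10, 4))
        fast_scores, fast_z = model.forward(X, S)
        slow_scores, slow_z = oracles.forward_loop(model, X, S.values)
        assert np.allclose(fast_scores.data, slow_scores, atol=1e-5)
        for a, b in zip(fast_z, slow_z):
            assert np.allclose(a.data, b, atol=1e-5)

    def test_bad_shapes_rejected_at_construction(self):
        with pytest.raises(ValueError, match="w="):
            ModelConfig(n_nodes=10, t_in=10, channels=(2, 2, 2), w=5, s=2,
                        attention_ratio=2)

    def test_wrong_input_shape_raises(self, rng):
        model = DstanModel(ModelConfig(n_nodes=6, t_in=16, channels=(2,),
                                       w=3, s=2, attention_ratio=2))
        with pytest.raises(ValueError, match="does not match"):
            model.forward(rng.standard_normal((2, 12, 6)), _adj(6))


def test_every_parameter_receives_gradient(rng):
    from dstan.training import total_loss
    cfg = ModelConfig(n_nodes=8, t_in=20, channels=(3, 4), w=3, s=2,
                      attention_ratio=2, seed=4)
    model = DstanModel(cfg)
    X = rng.standard_normal((6, 20, 8))
    y = np.array([0, 1, 0, 1, 0, 1])
    scores, zmaps = model.forward(X, _adj(8, rng))
    loss, _ = total_loss(scores, y, zmaps)
    backward(loss)
    for name, p in model.params.items():
        assert p.grad is not None and np.any(p.grad != 0), \
            f"no gradient reached {name}"


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = ModelConfig(n_nodes=6, t_in=16, channels=(2, 2), w=3, s=2,
                      attention_ratio=2, seed=9)
    model = DstanModel(cfg)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    loaded = DstanModel.load(path)
    assert loaded.cfg == cfg
    X = rng.standard_normal((2, 16, 6))
    S = _adj(6, rng)
    assert np.array_equal(model.forward(X, S)[0].data,
                          loaded.forward(X, S)[0].data)
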