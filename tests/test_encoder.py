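"""Transformer encoder: scalar-loop oracles, algebraic identities and
a finite-difference gradient audit."""

import numpy as np
import pytest

from emrjoint.autodiff import Tensor
from emrjoint.encoder import (
    AttentionParams,
    EncoderConfig,
    FfnParams,
    LayerNormParams,
    embed,
    encode,
    encoder_layer,
    feed_forward,
    init_encoder_params,
    layer_norm,
    multi_head_attention,
    scaled_dot_attention,
)


def tiny_config(**overrides) -> EncoderConfig:
    defaults = dict(vocab_size=11, L=1, h=8, m=2, d=12, max_n=16, seed=0)
    defaults.update(overrides)
    return EncoderConfig(**defaults)


# -- scaled dot-product attention -------------------------------------------


def attention_oracle(Q, K, V):
    """Independent scalar-loop attention: explicit softmax per row."""
    n, d_k = Q.shape
    out = np.zeros((n, V.shape[1]))
    weights = np.zeros((n, K.shape[0]))
    for i in range(n):
        logits = np.array(
            [sum(Q[i, t] * K[j, t] for t in range(d_k)) / np.sqrt(d_k)
             for j in range(K.shape[0])]
        )
        e = np.exp(logits - logits.max())
        weights[i] = e / e.sum()
        for j in range(K.shape[0]):
            out[i] += weights[i, j] * V[j]
    return out, weights


class TestScaledDotAttention:
    def test_constant_logits_give_uniform_weights(self):
        Q = np.ones((3, 2))
        K = np.ones((3, 2))
        V = np.arange(6.0).reshape(3, 2)
        out, weights = scaled_dot_attention(Q, K, V)
        assert np.allclose(weights.data, 1.0 / 3.0)
        assert np.allclose(out.data, V.mean(axis=0))

    def test_single_position_passes_value_through(self):
        out, weights = scaled_dot_attention(
            np.array([[1.0, 2.0]]), np.array([[0.5, 0.1]]), np.array([[7.0, -1.0]])
        )
        assert np.allclose(weights.data, [[1.0]])
        assert np.allclose(out.data, [[7.0, -1.0]])

    def test_matches_hand_computed_two_by_two(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 2.0]])
        out, weights = scaled_dot_attention(Q, K, V)
        oracle_out, oracle_w = attention_oracle(Q, K, V)
        # row 0 logits are {1/sqrt(2), 0}: softmax by hand
        w00 = np.exp(1 / np.sqrt(2)) / (np.exp(1 / np.sqrt(2)) + 1.0)
        assert np.isclose(weights.data[0, 0], w00)
        assert np.allclose(out.data, oracle_out, atol=1e-12)
        assert np.allclose(weights.data, oracle_w, atol=1e-12)

    def test_random_instances_match_scalar_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, d_k, d_v = rng.integers(1, 6, size=3)
            Q = rng.normal(size=(n, d_k))
            K = rng.normal(size=(n, d_k))
            V = rng.normal(size=(n, d_v))
            out, weights = scaled_dot_attention(Q, K, V)
            oracle_out, oracle_w = attention_oracle(Q, K, V)
            assert np.allclose(out.data, oracle_out, atol=1e-10)
            assert np.allclose(weights.data.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 2)))


# -- multi-head attention ----------------------------------------------------


class TestMultiHeadAttention:
    def test_single_identity_head_reduces_to_plain_attention(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(4, 3))
        eye = Tensor(np.eye(3), requires_grad=True)
        params = AttentionParams(W_Q=[eye], W_K=[eye], W_V=[eye], W_O=eye)
        out = multi_head_attention(Z, params)
        expected, _ = scaled_dot_attention(Z, Z, Z)
        assert np.allclose(out.data, expected.data, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        config = tiny_config()
        params = init_encoder_params(config).layers[0].attention
        Z = rng.normal(size=(5, config.h))
        perm = rng.permutation(5)
        out = multi_head_attention(Z, params).data
        out_perm = multi_head_attention(Z[perm], params).data
        assert np.allclose(out[perm], out_perm, atol=1e-12)

    def test_output_shape(self):
        config = tiny_config()
        params = init_encoder_params(config).layers[0].attention
        for n in (1, 3, 7):
            out = multi_head_attention(np.zeros((n, config.h)), params)
            assert out.shape == (n, config.h)


# -- feed-forward ------------------------------------------------------------


def ffn_oracle(Z, W1, b1, W2, b2):
    n, h = Z.shape
    d = W1.shape[1]
    out = np.zeros((n, W2.shape[1]))
    for i in range(n):
        hidden = np.zeros(d)
        for j in range(d):
            s = b1[j] + sum(Z[i, t] * W1[t, j] for t in range(h))
            hidden[j] = max(s, 0.0)
        for j in range(W2.shape[1]):
            out[i, j] = b2[j] + sum(hidden[t] * W2[t, j] for t in range(d))
    return out


class TestFeedForward:
    def test_zero_input_zero_bias_gives_zero(self):
        params = FfnParams(
            W1=Tensor(np.ones((3, 4))), b1=Tensor(np.zeros(4)),
            W2=Tensor(np.ones((4, 3))), b2=Tensor(np.zeros(3)),
        )
        assert np.allclose(feed_forward(np.zeros((2, 3)), params).data, 0.0)

    def test_identity_weights_pass_nonnegative_input(self):
        params = FfnParams(
            W1=Tensor(np.eye(3)), b1=Tensor(np.zeros(3)),
            W2=Tensor(np.eye(3)), b2=Tensor(np.zeros(3)),
        )
        Z = np.array([[0.0, 1.0, 2.0], [3.0, 0.5, 0.0]])
        assert np.allclose(feed_forward(Z, params).data, Z)

    def test_random_instance_matches_scalar_oracle(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(2, 3))
        W1, b1 = rng.normal(size=(3, 5)), rng.normal(size=5)
        W2, b2 = rng.normal(size=(5, 3)), rng.normal(size=3)
        params = FfnParams(W1=Tensor(W1), b1=Tensor(b1),
                           W2=Tensor(W2), b2=Tensor(b2))
        assert np.allclose(
            feed_forward(Z, params).data, ffn_oracle(Z, W1, b1, W2, b2),
            atol=1e-10,
        )


# -- layer norm --------------------------------------------------------------


class TestLayerNorm:
    def test_constant_row_maps_to_zero(self):
        params = LayerNormParams(G=Tensor(np.ones(4)), B=Tensor(np.zeros(4)),
                                 eps=1e-12)
        out = layer_norm(np.ones((1, 4)), params)
        assert np.allclose(out.data, 0.0, atol=1e-5)

    def test_two_value_row_standardizes_symmetrically(self):
        params = LayerNormParams(G=Tensor(np.ones(2)), B=Tensor(np.zeros(2)),
                                 eps=1e-15)
        out = layer_norm(np.array([[1.0, 3.0]]), params)
        assert np.allclose(out.data, [[-1.0, 1.0]], atol=1e-6)

    def test_affine_parameters_scale_and_shift(self):
        params = LayerNormParams(G=Tensor(np.full(2, 2.0)),
                                 B=Tensor(np.ones(2)), eps=1e-15)
        out = layer_norm(np.array([[1.0, 3.0]]), params)
        assert np.allclose(out.data, [[-1.0, 3.0]], atol=1e-6)

    def test_pre_affine_rows_have_zero_mean_unit_variance(self):
        rng = np.random.default_rng(3)
        h = 16
        params = LayerNormParams(G=Tensor(np.ones(h)), B=Tensor(np.zeros(h)),
                                 eps=1e-12)
        out = layer_norm(rng.normal(size=(6, h)) * 5 + 2, params).data
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(out.var(axis=1), 1.0, atol=1e-6)


# -- embedding, layer stacking, full encode ---------------------------------


class TestEmbed:
    def test_position_term_distinguishes_repeated_ids(self):
        config = tiny_config()
        params = init_encoder_params(config)
        X = embed([4, 4], config, params).data
        assert not np.allclose(X[0], X[1])

    def test_shape_and_determinism(self):
        config = tiny_config()
        a = embed([1], config, init_encoder_params(config)).data
        b = embed([1], config, init_encoder_params(config)).data
        assert a.shape == (1, config.h)
        assert np.array_equal(a, b)

    def test_out_of_range_and_overlength_rejected(self):
        config = tiny_config()
        params = init_encoder_params(config)
        with pytest.raises(ValueError):
            embed([config.vocab_size], config, params)
        with pytest.raises(ValueError):
            embed([0] * (config.max_n + 1), config, params)


class TestEncoderLayer:
    def test_preserves_shape(self):
        config = tiny_config()
        layer = init_encoder_params(config).layers[0]
        rng = np.random.default_rng(0)
        out = encoder_layer(rng.normal(size=(5, config.h)), layer)
        assert out.shape == (5, config.h)

    def test_zero_sublayers_reduce_to_double_layer_norm(self):
        config = tiny_config()
        layer = init_encoder_params(config).layers[0]
        for W in (layer.attention.W_Q + layer.attention.W_K
                  + layer.attention.W_V + [layer.attention.W_O]):
            W.data[:] = 0.0
        layer.ffn.W1.data[:] = 0.0
        layer.ffn.W2.data[:] = 0.0
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, config.h))
        out = encoder_layer(X, layer).data
        expected = layer_norm(layer_norm(X, layer.ln1), layer.ln2).data
        assert np.allclose(out, expected, atol=1e-12)

    def test_matches_composition_of_audited_sub_operations(self):
        config = tiny_config(h=4, m=2, d=6)
        layer = init_encoder_params(config).layers[0]
        rng = np.random.default_rng(9)
        X = rng.normal(size=(3, 4))
        U = layer_norm(
            Tensor(X) + multi_head_attention(X, layer.attention), layer.ln1
        )
        expected = layer_norm(U + feed_forward(U, layer.ffn), layer.ln2).data
        assert np.array_equal(encoder_layer(X, layer).data, expected)


class TestEncode:
    def test_zero_layers_equals_embedding(self):
        config = tiny_config(L=0)
        params = init_encoder_params(config)
        ids = [3, 1, 4]
        assert np.array_equal(
            encode(ids, config, params).data, embed(ids, config, params).data
        )

    def test_two_layers_equal_two_applications(self):
        config = tiny_config(L=2)
        params = init_encoder_params(config)
        ids = [2, 7, 1]
        manual = embed(ids, config, params)
        for layer in params.layers:
            manual = encoder_layer(manual, layer)
        assert np.array_equal(encode(ids, config, params).data, manual.data)

    def test_deterministic_across_runs(self):
        config = tiny_config(L=2)
        a = encode([1, 2, 3], config, init_encoder_params(config)).data
        b = encode([1, 2, 3], config, init_encoder_params(config)).data
        assert np.array_equal(a, b)

    def test_outputs_finite_across_random_configurations(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = int(rng.integers(1, 4))
            config = EncoderConfig(
                vocab_size=int(rng.integers(3, 12)),
                L=int(rng.integers(0, 3)),
                h=m * int(rng.integers(2, 5)),
                m=m,
                d=int(rng.integers(2, 10)),
                max_n=12,
                seed=int(rng.integers(1000)),
            )
            params = init_encoder_params(config)
            n = int(rng.integers(1, config.max_n + 1))
            ids = rng.integers(config.vocab_size, size=n)
            assert np.all(np.isfinite(encode(ids, config, params).data))


def test_finite_difference_gradient_through_encoder():
    """Analytic gradients through a 1-layer encoder match central
    differences within 1e-4 relative error."""
    config = tiny_config(L=1, h=8, m=2, d=12)
    params = init_encoder_params(config)
    ids = [3, 1, 4, 1]
    rng = np.random.default_rng(42)
    R = rng.normal(size=(len(ids), config.h))

    def loss_value() -> float:
        return float((encode(ids, config, params).data * R).sum())

    loss = (encode(ids, config, params) * Tensor(R)).sum()
    loss.backward()

    eps = 1e-6
    for tensor in params.tensors():
        flat = tensor.data.reshape(-1)
        n_checks = min(flat.size, 6)
        idxs = rng.choice(flat.size, size=n_checks, replace=False)
        for idx in idxs:
            orig = flat[idx]
            flat[idx] = orig + eps
            hi = loss_value()
            flat[idx] = orig - eps
            lo = loss_value()
            flat[idx] = orig
            numeric = (hi - lo) / (2 * eps)
            analytic = tensor.grad.reshape(-1)[idx]
            denom = max(abs(numeric), abs(analytic), 1.0)
            assert abs(numeric - analytic) / denom < 1e-4
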