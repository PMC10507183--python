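"""Transformer encoder built from scratch on the autodiff core.

An L-layer post-norm encoder: learned token + absolute position
embeddings, multi-head scaled dot-product self-attention, a two-layer
ReLU feed-forward sublayer, with a residual connection and layer
normalization around each sublayer:

    U = LN(X + MHA(X));   Y = LN(U + FFN(U))

Heads use d_k = d_v = h / m. Layer normalization standardizes each row
(token position) before a learned affine map. All parameters are
initialized from a symmetric uniform range scaled by fan-in, driven by a
single seed, so forward passes are bit-reproducible. Dropout is omitted:
the models trained here are small and determinism is worth more than
regularization at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat, softmax

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "init_encoder_params",
    "embed",
    "scaled_dot_attention",
    "multi_head_attention",
    "feed_forward",
    "layer_norm",
    "encoder_layer",
    "encode",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    h must be divisible by m; per-head key/value dims are h // m.
    """

    vocab_size: int
    L: int = 2
    h: int = 64
    m: int = 4
    d: int = 128
    max_n: int = 128
    eps: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.h % self.m != 0:
            raise ValueError(f"hidden size {self.h} not divisible by {self.m} heads")
        if min(self.vocab_size, self.L + 1, self.h, self.m, self.d, self.max_n) <= 0:
            raise ValueError("all dimensions must be positive (L may be 0)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @property
    def d_k(self) -> int:
        return self.h // self.m

    @property
    def d_v(self) -> int:
        return self.h // self.m

    def to_dict(self) -> dict:
        return {
            "vocab_size": self.vocab_size, "L": self.L, "h": self.h,
            "m": self.m, "d": self.d, "max_n": self.max_n,
            "eps": self.eps, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EncoderConfig":
        return cls(**payload)


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


@dataclass
class AttentionParams:
    W_Q: list[Tensor]
    W_K: list[Tensor]
    W_V: list[Tensor]
    W_O: Tensor


@dataclass
class FfnParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor


@dataclass
class LayerNormParams:
    G: Tensor
    B: Tensor
    eps: float


@dataclass
class EncoderLayerParams:
    attention: AttentionParams
    ln1: LayerNormParams
    ffn: FfnParams
    ln2: LayerNormParams


@dataclass
class EncoderParams:
    token_embedding: Tensor  # (vocab_size, h)
    position_embedding: Tensor  # (max_n, h)
    layers: list[EncoderLayerParams] = field(default_factory=list)

    def tensors(self) -> list[Tensor]:
        out = [self.token_embedding, self.position_embedding]
        for layer in self.layers:
            out.extend(layer.attention.W_Q)
            out.extend(layer.attention.W_K)
            out.extend(layer.attention.W_V)
            out.append(layer.attention.W_O)
            out.extend([layer.ln1.G, layer.ln1.B])
            out.extend([layer.ffn.W1, layer.ffn.b1, layer.ffn.W2, layer.ffn.b2])
            out.extend([layer.ln2.G, layer.ln2.B])
        return out


def init_encoder_params(config: EncoderConfig) -> EncoderParams:
    """Seeded fan-in-scaled uniform init; biases zero, LN gain one."""
    rng = np.random.default_rng(config.seed)
    h, d, dk = config.h, config.d, config.d_k
    params = EncoderParams(
        token_embedding=_uniform(rng, (config.vocab_size, h), h),
        position_embedding=_uniform(rng, (config.max_n, h), h),
    )
    for _ in range(config.L):
        attention = AttentionParams(
            W_Q=[_uniform(rng, (h, dk), h) for _ in range(config.m)],
            W_K=[_uniform(rng, (h, dk), h) for _ in range(config.m)],
            W_V=[_uniform(rng, (h, dk), h) for _ in range(config.m)],
            W_O=_uniform(rng, (h, h), h),
        )
        ffn = FfnParams(
            W1=_uniform(rng, (h, d), h),
            b1=Tensor(np.zeros(d), requires_grad=True),
            W2=_uniform(rng, (d, h), d),
            b2=Tensor(np.zeros(h), requires_grad=True),
        )
        params.layers.append(
            EncoderLayerParams(
                attention=attention,
                ln1=LayerNormParams(
                    G=Tensor(np.ones(h), requires_grad=True),
                    B=Tensor(np.zeros(h), requires_grad=True),
                    eps=config.eps,
                ),
                ffn=ffn,
                ln2=LayerNormParams(
                    G=Tensor(np.ones(h), requires_grad=True),
                    B=Tensor(np.zeros(h), requires_grad=True),
                    eps=config.eps,
                ),
            )
        )
    return params


def embed(ids, config: EncoderConfig, params: EncoderParams) -> Tensor:
    """X^(0): token embedding plus learned absolute position embedding."""
    ids = np.asarray(ids, dtype=np.intp)
    if ids.ndim != 1 or ids.size == 0:
        raise ValueError("ids must be a non-empty 1-D sequence")
    if ids.max() >= config.vocab_size or ids.min() < 0:
        raise ValueError("token id out of vocabulary range")
    n = ids.size
    if n > config.max_n:
        raise ValueError(f"sequence length {n} exceeds max_n {config.max_n}")
    return params.token_embedding[ids] + params.position_embedding.take_rows(0, n)


def scaled_dot_attention(Q, K, V) -> tuple[Tensor, Tensor]:
    """Softmax(Q K^T / sqrt(d_k)) V; returns (output, attention weights)."""
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    if Q.shape[1] != K.shape[1]:
        raise ValueError(
            f"Q has d_k={Q.shape[1]} but K has d_k={K.shape[1]}"
        )
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    d_k = Q.shape[1]
    logits = (Q @ K.T) / float(np.sqrt(d_k))
    weights = softmax(logits, axis=1)
    return weights @ V, weights


def multi_head_attention(Z, params: AttentionParams) -> Tensor:
    """Concat of per-head scaled-dot attention, projected by W_O."""
    Z = as_tensor(Z)
    h = Z.shape[1]
    if params.W_O.shape != (h, h):
        raise ValueError("W_O shape incompatible with hidden size")
    heads = []
    for W_Q, W_K, W_V in zip(params.W_Q, params.W_K, params.W_V):
        if W_Q.shape[0] != h:
            raise ValueError("head projection incompatible with hidden size")
        out, _ = scaled_dot_attention(Z @ W_Q, Z @ W_K, Z @ W_V)
        heads.append(out)
    if sum(head.shape[1] for head in heads) != h:
        raise ValueError("concatenated head dims must equal hidden size")
    return concat(heads, axis=1) @ params.W_O


def feed_forward(Z, params: FfnParams) -> Tensor:
    """Two-layer position-wise network: ReLU(Z W1 + b1) W2 + b2."""
    Z = as_tensor(Z)
    if Z.shape[1] != params.W1.shape[0]:
        raise ValueError("input width incompatible with W1")
    return (Z @ params.W1 + params.b1).relu() @ params.W2 + params.b2


def layer_norm(Z, params: LayerNormParams) -> Tensor:
    """Per-row standardization followed by the learned G/B affine map."""
    Z = as_tensor(Z)
    if Z.shape[1] != params.G.shape[0]:
        raise ValueError("input width incompatible with layer-norm params")
    mu = Z.mean(axis=1, keepdims=True)
    centered = Z - mu
    var = (centered * centered).mean(axis=1, keepdims=True)
    return params.G * (centered / (var + params.eps).sqrt()) + params.B


def encoder_layer(X, params: EncoderLayerParams) -> Tensor:
    """Post-norm block: LN(X + MHA(X)) then LN(U + FFN(U))."""
    X = as_tensor(X)
    U = layer_norm(X + multi_head_attention(X, params.attention), params.ln1)
    return layer_norm(U + feed_forward(U, params.ffn), params.ln2)


def encode(ids, config: EncoderConfig, params: EncoderParams) -> Tensor:
    """Embed then apply the L encoder layers; returns Y^(L) of shape (n, h)."""
    Y = embed(ids, config, params)
    for layer in params.layers:
        Y = encoder_layer(Y, layer)
    return Y
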