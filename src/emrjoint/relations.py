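"""Relation-classification head: span gathering, bilinear attention
pooling, pair scoring and decoding.

For each ordered candidate pair of entity spans the head:

1. gathers the encoder rows of each span (``Gather``);
2. pools each span into one vector through a bilinear cross-attention:
   compatibility ``S[i, j] = u_i W_B v_j``; the head span is pooled with
   weights ``softmax_i(max_j S[i, j])`` and the tail span with
   ``softmax_j(max_i S[i, j])``;
3. concatenates the two pooled vectors into a 2h pair representation;
4. scores it linearly against r relation classes (the substantive
   relation types plus a reserved NO_RELATION null class at index 0).

Decoding is per pair: either argmax over classes (a relation is emitted
unless the null class wins) or a probability threshold on the best
non-null class. Training minimizes mean cross-entropy over candidate
pairs, with gold entity spans as inputs (teacher forcing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, concat, logsumexp, softmax
from .corpus import EntitySpan, LabelScheme, RelationInstance

__all__ = [
    "CandidatePair",
    "ReParameters",
    "init_re_params",
    "enumerate_candidate_pairs",
    "gather_span_vectors",
    "bilinear_attention_pool",
    "pair_representation",
    "relation_scores",
    "softmax_re",
    "decode_relations",
    "re_loss",
]

MAX_CANDIDATE_PAIRS = 200  # deterministic truncation cap per document


@dataclass(frozen=True)
class CandidatePair:
    head: EntitySpan
    tail: EntitySpan


@dataclass
class ReParameters:
    """Bilinear pooling matrix plus the linear class scorer."""

    W_B: Tensor  # (h, h)
    W_R: Tensor  # (2h, r)
    b_R: Tensor  # (r,)


def init_re_params(h: int, r: int, seed: int = 0) -> ReParameters:
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(h)
    bound2 = 1.0 / np.sqrt(2 * h)
    return ReParameters(
        W_B=Tensor(rng.uniform(-bound, bound, size=(h, h)), requires_grad=True),
        W_R=Tensor(rng.uniform(-bound2, bound2, size=(2 * h, r)), requires_grad=True),
        b_R=Tensor(np.zeros(r), requires_grad=True),
    )


def enumerate_candidate_pairs(
    entities: Sequence[EntitySpan],
    scheme: LabelScheme | None = None,
    type_constraints: set[tuple[str, str]] | None = None,
    max_pairs: int = MAX_CANDIDATE_PAIRS,
) -> list[CandidatePair]:
    """All ordered pairs (a, b), a != b, in (head index, tail index) order.

    When ``type_constraints`` is given, only pairs whose
    (head type, tail type) appears in it are kept. The list is truncated
    deterministically at ``max_pairs``.
    """
    pairs: list[CandidatePair] = []
    for i, head in enumerate(entities):
        for j, tail in enumerate(entities):
            if i == j:
                continue
            if type_constraints is not None and (
                head.label,
                tail.label,
            ) not in type_constraints:
                continue
            pairs.append(CandidatePair(head=head, tail=tail))
            if len(pairs) >= max_pairs:
                return pairs
    return pairs


def gather_span_vectors(Y, span: EntitySpan) -> Tensor:
    """Rows ``start..end-1`` of the encoder output, order preserved."""
    Y = as_tensor(Y)
    n = Y.shape[0]
    if not (0 <= span.start < span.end <= n):
        raise ValueError(
            f"span [{span.start}, {span.end}) out of range for {n} positions"
        )
    return Y.take_rows(span.start, span.end)


def bilinear_attention_pool(U_head, U_tail, W_B) -> Tensor:
    """Pool two spans into a 2h pair representation.

    Compatibility S = U_head W_B U_tail^T; each side is pooled with a
    softmax over its max compatibility with the other side, and the two
    pooled vectors are concatenated. Single-token spans reduce exactly to
    concatenation of the two rows; W_B = 0 reduces to mean pooling.
    """
    U_head, U_tail, W_B = as_tensor(U_head), as_tensor(U_tail), as_tensor(W_B)
    if U_head.shape[0] < 1 or U_tail.shape[0] < 1:
        raise ValueError("spans must contain at least one token")
    if U_head.shape[1] != W_B.shape[0] or U_tail.shape[1] != W_B.shape[1]:
        raise ValueError("hidden size incompatible with W_B")
    S = U_head @ W_B @ U_tail.T  # (p, q)
    a = softmax(S.max(axis=1), axis=0)  # (p,)
    b = softmax(S.max(axis=0), axis=0)  # (q,)
    e_head = a.reshape(1, -1) @ U_head  # (1, h)
    e_tail = b.reshape(1, -1) @ U_tail  # (1, h)
    return concat([e_head, e_tail], axis=1).reshape(-1)  # (2h,)


def pair_representation(Y, pair: CandidatePair, params: ReParameters) -> Tensor:
    return bilinear_attention_pool(
        gather_span_vectors(Y, pair.head),
        gather_span_vectors(Y, pair.tail),
        params.W_B,
    )


def relation_scores(pair_vectors: Sequence, params: ReParameters) -> Tensor:
    """Stack pair vectors and score them: (m, r) matrix, row = v W_R + b_R."""
    r = params.W_R.shape[1]
    if len(pair_vectors) == 0:
        return Tensor(np.zeros((0, r)))
    rows = [as_tensor(v).reshape(1, -1) for v in pair_vectors]
    stacked = concat(rows, axis=0)
    if stacked.shape[1] != params.W_R.shape[0]:
        raise ValueError("pair representation width incompatible with W_R")
    return stacked @ params.W_R + params.b_R


def softmax_re(pair_vector, params: ReParameters) -> Tensor:
    """Class probabilities for one pair via the softmax layer (length r)."""
    v = as_tensor(pair_vector).reshape(1, -1)
    if v.shape[1] != params.W_R.shape[0]:
        raise ValueError("pair representation width incompatible with W_R")
    return softmax(v @ params.W_R + params.b_R, axis=1).reshape(-1)


def decode_relations(
    scores,
    pairs: Sequence[CandidatePair],
    scheme: LabelScheme,
    strategy: str = "argmax",
    tau: float = 0.5,
) -> list[RelationInstance]:
    """Turn the (m, r) score matrix into relation instances.

    ``argmax``: per pair emit the highest-scoring class unless it is the
    null class; ties break toward the lowest class index. ``threshold``:
    emit the best non-null class iff its softmax probability >= tau.
    """
    if strategy not in ("argmax", "threshold"):
        raise ValueError(f"unknown decoding strategy {strategy!r}")
    scores = as_tensor(scores).data
    if scores.shape[0] != len(pairs):
        raise ValueError("one score row per candidate pair required")
    relations: list[RelationInstance] = []
    for row, pair in zip(scores, pairs):
        if strategy == "argmax":
            best = int(row.argmax())  # first max = lowest class index
            if best == 0:
                continue
            label = scheme.relation_label(best)
        elif strategy == "threshold":
            shifted = row - row.max()
            probs = np.exp(shifted) / np.exp(shifted).sum()
            best = 1 + int(probs[1:].argmax())
            if probs[best] < tau:
                continue
            label = scheme.relation_label(best)
        else:
            raise ValueError(f"unknown decoding strategy {strategy!r}")
        relations.append(
            RelationInstance(head=pair.head.id, tail=pair.tail.id, label=label)
        )
    return relations


def re_loss(scores, gold_labels: Sequence[int]) -> Tensor:
    """Mean cross-entropy of row-softmax(scores) against gold class ids.

    Zero candidate pairs contribute zero loss by convention.
    """
    scores = as_tensor(scores)
    m, r = scores.shape
    gold = np.asarray(gold_labels, dtype=np.intp)
    if gold.size != m:
        raise ValueError("one gold class per candidate pair required")
    if m == 0:
        return Tensor(0.0)
    if gold.min() < 0 or gold.max() >= r:
        raise ValueError("gold relation class out of range")
    log_z = logsumexp(scores, axis=1)
    gold_scores = scores[(np.arange(m), gold)]
    return (log_z - gold_scores).sum() / float(m)
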