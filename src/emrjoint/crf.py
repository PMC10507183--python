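"""Entity-labeling head: emission projection + linear-chain CRF.

Emissions are a linear projection of the encoder output, ``Y W_E + b_E``
of shape (n, c) for c BIO tags. A path's score is

    trans(START -> t_1) + sum_i emis[i, t_i]
    + sum_i trans(t_i -> t_{i+1}) + trans(t_n -> STOP)

with explicit augmented START/STOP states. The normalizer over all c^n
paths is computed by the forward recursion in log space; training
minimizes the negative log-likelihood (log-partition minus gold path
score); decoding uses the Viterbi algorithm with ties broken toward the
lowest tag index.

A hard BIO structure mask (on by default) sets transitions into ``I-X``
from anything other than ``B-X``/``I-X`` to -inf, so decoded sequences
are always well-formed span encodings. Masked entries receive zero
gradient and stay -inf throughout training.

A plain softmax tagging layer is provided as a configurable alternative
to the CRF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, logsumexp, softmax
from .corpus import LabelScheme

__all__ = [
    "CrfParameters",
    "init_crf_params",
    "bio_transition_mask",
    "ner_emissions",
    "crf_path_score",
    "crf_log_partition",
    "crf_nll",
    "viterbi_decode",
    "softmax_ner",
    "softmax_ner_nll",
]

NEG_INF = -1e30  # effectively -inf but keeps arithmetic NaN-free


@dataclass
class CrfParameters:
    """Emission projection plus (c+2, c+2) transition matrix.

    Transition state order: the c BIO tags, then START (index c), then
    STOP (index c+1). Transitions into START and out of STOP are masked.
    """

    W_E: Tensor  # (h, c)
    b_E: Tensor  # (c,)
    transitions: Tensor  # (c + 2, c + 2)

    @property
    def num_tags(self) -> int:
        return self.W_E.shape[1]

    @property
    def start(self) -> int:
        return self.num_tags

    @property
    def stop(self) -> int:
        return self.num_tags + 1


def bio_transition_mask(scheme: LabelScheme) -> np.ndarray:
    """Boolean (c+2, c+2) matrix: True where a transition is allowed.

    Forbids entering ``I-X`` from any state other than ``B-X`` or
    ``I-X`` (this covers O -> I-X, B-Y -> I-X, I-Y -> I-X and
    START -> I-X), plus the structural START/STOP constraints.
    """
    c = scheme.num_tags
    start, stop = c, c + 1
    allowed = np.ones((c + 2, c + 2), dtype=bool)
    allowed[:, start] = False  # nothing enters START
    allowed[stop, :] = False  # nothing leaves STOP
    allowed[start, stop] = False  # sequences are non-empty
    for j, tag in enumerate(scheme.bio_tags):
        if not tag.startswith("I-"):
            continue
        etype = tag[2:]
        legal_prev = {f"B-{etype}", f"I-{etype}"}
        for i in range(c):
            if scheme.bio_tags[i] not in legal_prev:
                allowed[i, j] = False
        allowed[start, j] = False
    return allowed


def init_crf_params(
    scheme: LabelScheme, h: int, seed: int = 0, bio_mask: bool = True
) -> CrfParameters:
    rng = np.random.default_rng(seed)
    c = scheme.num_tags
    bound = 1.0 / np.sqrt(h)
    trans = rng.uniform(-0.1, 0.1, size=(c + 2, c + 2))
    allowed = bio_transition_mask(scheme) if bio_mask else _structural_mask(c)
    trans[~allowed] = NEG_INF
    return CrfParameters(
        W_E=Tensor(rng.uniform(-bound, bound, size=(h, c)), requires_grad=True),
        b_E=Tensor(np.zeros(c), requires_grad=True),
        transitions=Tensor(trans, requires_grad=True),
    )


def _structural_mask(c: int) -> np.ndarray:
    allowed = np.ones((c + 2, c + 2), dtype=bool)
    allowed[:, c] = False
    allowed[c + 1, :] = False
    allowed[c, c + 1] = False
    return allowed


def ner_emissions(Y, params: CrfParameters) -> Tensor:
    """Project encoder output to per-position tag scores (n, c)."""
    Y = as_tensor(Y)
    if Y.shape[1] != params.W_E.shape[0]:
        raise ValueError("hidden size incompatible with emission projection")
    return Y @ params.W_E + params.b_E


def _check_tags(emissions, tags) -> np.ndarray:
    tags = np.asarray(tags, dtype=np.intp)
    n, c = emissions.shape
    if tags.ndim != 1 or tags.size != n:
        raise ValueError(f"tag sequence length {tags.size} != {n} positions")
    if tags.size and (tags.min() < 0 or tags.max() >= c):
        raise ValueError("tag index out of range")
    return tags


def crf_path_score(emissions, transitions, tags) -> Tensor:
    """Score of one tag path, including START/STOP transitions."""
    emissions = as_tensor(emissions)
    transitions = as_tensor(transitions)
    tags = _check_tags(emissions, tags)
    n, c = emissions.shape
    start, stop = c, c + 1
    emit = emissions[(np.arange(n), tags)].sum()
    prev = np.concatenate(([start], tags))
    nxt = np.concatenate((tags, [stop]))
    return emit + transitions[(prev, nxt)].sum()


def crf_log_partition(emissions, transitions) -> Tensor:
    """log sum over all c^n paths of exp(path score), by forward recursion."""
    emissions = as_tensor(emissions)
    transitions = as_tensor(transitions)
    n, c = emissions.shape
    if n < 1:
        raise ValueError("need at least one position")
    start, stop = c, c + 1
    alpha = transitions[(start, slice(0, c))] + emissions[0]
    inner = transitions[(slice(0, c), slice(0, c))]
    for t in range(1, n):
        alpha = logsumexp(alpha.reshape(c, 1) + inner, axis=0) + emissions[t]
    return logsumexp(alpha + transitions[(slice(0, c), stop)], axis=0)


def crf_nll(emissions, transitions, gold) -> Tensor:
    """Negative log-likelihood of the gold path; nonnegative."""
    return crf_log_partition(emissions, transitions) - crf_path_score(
        emissions, transitions, gold
    )


def viterbi_decode(emissions, transitions) -> tuple[list[int], float]:
    """Maximum-scoring tag path and its score.

    Dynamic program on raw scores (no gradients). Ties are broken toward
    the lowest tag index at every backtracking step.
    """
    emissions = as_tensor(emissions).data
    transitions = as_tensor(transitions).data
    n, c = emissions.shape
    start, stop = c, c + 1
    inner = transitions[:c, :c]
    score = transitions[start, :c] + emissions[0]
    backpointers = np.zeros((n, c), dtype=np.intp)
    for t in range(1, n):
        candidate = score[:, None] + inner  # (from, to)
        backpointers[t] = candidate.argmax(axis=0)  # first max = lowest index
        score = candidate.max(axis=0) + emissions[t]
    final = score + transitions[:c, stop]
    best = int(final.argmax())
    path = [best]
    for t in range(n - 1, 0, -1):
        best = int(backpointers[t, best])
        path.append(best)
    path.reverse()
    return path, float(final.max())


def softmax_ner(Y, W_ner, b_ner) -> Tensor:
    """Per-position tag posteriors via a plain softmax layer (n, c)."""
    Y = as_tensor(Y)
    W_ner, b_ner = as_tensor(W_ner), as_tensor(b_ner)
    if Y.shape[1] != W_ner.shape[0]:
        raise ValueError("hidden size incompatible with softmax projection")
    return softmax(Y @ W_ner + b_ner, axis=1)


def softmax_ner_nll(Y, W_ner, b_ner, gold) -> Tensor:
    """Mean per-token cross-entropy for the softmax tagging head."""
    Y = as_tensor(Y)
    logits = Y @ as_tensor(W_ner) + as_tensor(b_ner)
    gold = _check_tags(logits, gold)
    n = logits.shape[0]
    log_z = logsumexp(logits, axis=1)
    gold_scores = logits[(np.arange(n), gold)]
    return (log_z - gold_scores).sum() / float(n)
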