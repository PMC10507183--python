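"""Functional wrappers around :class:`~emrjoint.model.JointExtractor`.

These are the procedural entry points the CLI uses: split a corpus
80/20, train a joint model, predict on raw token sequences. They stay
thin — all modeling lives in the estimator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .corpus import AnnotatedDocument
from .model import JointExtractor, LossComponents, joint_loss

__all__ = ["joint_loss", "LossComponents", "split_corpus", "train", "predict"]


def split_corpus(
    docs: Sequence[AnnotatedDocument],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Seeded shuffle, then a floor(train_fraction * N) / rest split.

    The two parts are disjoint and exhaustive; the same seed always
    yields the same partition.
    """
    docs = list(docs)
    if len(docs) < 2:
        raise ValueError("need at least 2 documents to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    order = np.random.default_rng(seed).permutation(len(docs))
    n_train = int(np.floor(train_fraction * len(docs)))
    train = [docs[i] for i in order[:n_train]]
    test = [docs[i] for i in order[n_train:]]
    return train, test


def train(
    corpus: Sequence[AnnotatedDocument],
    eval_docs: Sequence[AnnotatedDocument] | None = None,
    **hyperparams,
) -> tuple[JointExtractor, list[dict]]:
    """Fit a JointExtractor; returns the model and its epoch history."""
    model = JointExtractor(**hyperparams)
    model.fit(list(corpus), eval_docs=eval_docs)
    return model, model.history_


def predict(
    model: JointExtractor, token_sequences: Sequence[Sequence[str]]
) -> list[AnnotatedDocument]:
    return model.predict(token_sequences)
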