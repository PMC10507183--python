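"""Joint entity/relation extractor with a shared encoder.

:class:`JointExtractor` is a scikit-learn-style estimator: configure it
with hyperparameters, ``fit`` it on a list of annotated documents, and
``predict`` entities and relations for new token sequences. One
transformer encoder feeds two task heads — a CRF (or softmax) tagger and
a bilinear-attention relation classifier — trained jointly by minimizing
the unweighted sum of the two task losses:

    Loss = Loss_ner + Loss_re

Each optimizer step therefore pushes gradients from both tasks into the
shared encoder. Training uses gold entity spans as relation-head inputs
(teacher forcing); prediction runs the full pipeline: encode ->
Viterbi-decode tags -> spans -> candidate pairs -> relation scores ->
decode. All randomness (initialization, shuffling) flows from one root
seed, so runs are bit-reproducible on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import crf as crf_mod
from . import encoder as enc_mod
from . import relations as re_mod
from .autodiff import Tensor
from .corpus import (
    AnnotatedDocument,
    LabelScheme,
    bio_to_spans,
    spans_to_bio,
)

__all__ = ["JointExtractor", "LossComponents", "joint_loss"]

UNK = "<UNK>"


@dataclass(frozen=True)
class LossComponents:
    """The two task losses and their sum (exact, per the joint objective)."""

    loss_ner: float
    loss_re: float
    loss: float


def joint_loss(loss_ner: float, loss_re: float) -> LossComponents:
    """Unweighted multi-task objective: Loss = Loss_ner + Loss_re."""
    if not (np.isfinite(loss_ner) and np.isfinite(loss_re)):
        raise ValueError("loss components must be finite")
    return LossComponents(
        loss_ner=float(loss_ner),
        loss_re=float(loss_re),
        loss=float(loss_ner) + float(loss_re),
    )


class _Adam:
    """Adam optimizer over a fixed list of Tensors."""

    def __init__(self, tensors: list[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.tensors = tensors
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, tensor in enumerate(self.tensors):
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for tensor in self.tensors:
            tensor.grad = None


class _SGD:
    """Plain gradient descent; kept for gradient-audit tests."""

    def __init__(self, tensors: list[Tensor], lr: float):
        self.tensors = tensors
        self.lr = lr

    def step(self) -> None:
        for tensor in self.tensors:
            if tensor.grad is not None:
                tensor.data -= self.lr * tensor.grad

    def zero_grad(self) -> None:
        for tensor in self.tensors:
            tensor.grad = None


class JointExtractor(BaseEstimator):
    """Joint NER + RE model over a shared transformer encoder.

    Parameters
    ----------
    L, h, m, d, max_n, eps : encoder architecture (layers, hidden size,
        attention heads, feed-forward inner size, max sequence length,
        layer-norm stabilizer).
    epochs, batch_size, learning_rate, optimizer : training schedule.
        ``optimizer`` is ``"adam"`` (default) or ``"sgd"``.
    ner_loss : ``"crf"`` (Viterbi-decoded CRF head, default) or
        ``"softmax"`` (independent per-token classifier).
    re_strategy, tau : relation decoding — ``"argmax"`` (default) or
        ``"threshold"`` with probability threshold ``tau``.
    task : ``"joint"`` (default), ``"ner"`` or ``"re"`` — single-task
        ablations zero the other head's loss.
    bio_mask : forbid structurally invalid BIO transitions in the CRF.
    seed : root seed for initialization and shuffling.

    Fitted attributes (trailing underscore) include the vocabulary
    ``vocab_``, label scheme ``scheme_``, parameter containers and the
    per-epoch ``history_``.
    """

    def __init__(
        self,
        L: int = 2,
        h: int = 64,
        m: int = 4,
        d: int = 128,
        max_n: int = 128,
        eps: float = 1e-5,
        epochs: int = 30,
        batch_size: int = 8,
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        ner_loss: str = "crf",
        re_strategy: str = "argmax",
        tau: float = 0.5,
        task: str = "joint",
        bio_mask: bool = True,
        seed: int = 0,
    ):
        self.L = L
        self.h = h
        self.m = m
        self.d = d
        self.max_n = max_n
        self.eps = eps
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.ner_loss = ner_loss
        self.re_strategy = re_strategy
        self.tau = tau
        self.task = task
        self.bio_mask = bio_mask
        self.seed = seed

    # -- setup ---------------------------------------------------------------

    def _validate_hyperparams(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.ner_loss not in ("crf", "softmax"):
            raise ValueError(f"unknown ner_loss {self.ner_loss!r}")
        if self.re_strategy not in ("argmax", "threshold"):
            raise ValueError(f"unknown re_strategy {self.re_strategy!r}")
        if self.task not in ("joint", "ner", "re"):
            raise ValueError(f"unknown task mode {self.task!r}")

    def _build(self, docs: list[AnnotatedDocument],
               scheme: LabelScheme | None) -> None:
        tokens = sorted({tok for doc in docs for tok in doc.tokens})
        self.vocab_ = {UNK: 0}
        for tok in tokens:
            self.vocab_[tok] = len(self.vocab_)
        if scheme is None:
            scheme = LabelScheme(
                entity_types=tuple(
                    sorted({e.label for doc in docs for e in doc.entities})
                ),
                relation_types=tuple(
                    sorted({r.label for doc in docs for r in doc.relations})
                ),
            )
        self.scheme_ = scheme
        self.config_ = enc_mod.EncoderConfig(
            vocab_size=len(self.vocab_), L=self.L, h=self.h, m=self.m,
            d=self.d, max_n=self.max_n, eps=self.eps, seed=self.seed,
        )
        self.encoder_params_ = enc_mod.init_encoder_params(self.config_)
        self.crf_params_ = crf_mod.init_crf_params(
            scheme, self.h, seed=self.seed + 1, bio_mask=self.bio_mask
        )
        self.softmax_ner_params_ = self._init_softmax_ner(seed=self.seed + 3)
        self.re_params_ = re_mod.init_re_params(
            self.h, scheme.num_relation_classes, seed=self.seed + 2
        )

    def _init_softmax_ner(self, seed: int) -> tuple[Tensor, Tensor]:
        rng = np.random.default_rng(seed)
        c = self.scheme_.num_tags
        bound = 1.0 / np.sqrt(self.h)
        return (
            Tensor(rng.uniform(-bound, bound, size=(self.h, c)), requires_grad=True),
            Tensor(np.zeros(c), requires_grad=True),
        )

    def _tensors(self) -> list[Tensor]:
        out = self.encoder_params_.tensors()
        out += [self.crf_params_.W_E, self.crf_params_.b_E,
                self.crf_params_.transitions]
        out += list(self.softmax_ner_params_)
        out += [self.re_params_.W_B, self.re_params_.W_R, self.re_params_.b_R]
        return out

    def _ids(self, tokens) -> np.ndarray:
        return np.array([self.vocab_.get(tok, 0) for tok in tokens], dtype=np.intp)

    # -- losses ---------------------------------------------------------------

    def _doc_losses(self, doc: AnnotatedDocument) -> tuple[Tensor, Tensor]:
        """(ner loss, re loss) graph nodes for one document."""
        Y = enc_mod.encode(self._ids(doc.tokens), self.config_, self.encoder_params_)
        zero = Tensor(0.0)

        ner = zero
        if self.task in ("joint", "ner"):
            gold_tags = [
                self.scheme_.tag_index(t)
                for t in spans_to_bio(doc, self.scheme_)
            ]
            if self.ner_loss == "crf":
                emissions = crf_mod.ner_emissions(Y, self.crf_params_)
                ner = crf_mod.crf_nll(
                    emissions, self.crf_params_.transitions, gold_tags
                ) / float(len(doc.tokens))
            else:
                W, b = self.softmax_ner_params_
                ner = crf_mod.softmax_ner_nll(Y, W, b, gold_tags)

        re = zero
        if self.task in ("joint", "re"):
            pairs = re_mod.enumerate_candidate_pairs(doc.entities)
            if pairs:
                vectors = [
                    re_mod.pair_representation(Y, pair, self.re_params_)
                    for pair in pairs
                ]
                scores = re_mod.relation_scores(vectors, self.re_params_)
                gold_by_pair = {
                    (r.head, r.tail): self.scheme_.relation_index(r.label)
                    for r in doc.relations
                }
                gold = [
                    gold_by_pair.get((p.head.id, p.tail.id), 0) for p in pairs
                ]
                re = re_mod.re_loss(scores, gold)
        return ner, re

    # -- estimator API ---------------------------------------------------------

    def fit(self, X, y=None, eval_docs=None):
        """Train on a list of AnnotatedDocuments.

        ``eval_docs`` (optional) is a held-out corpus evaluated after
        each epoch; its strict micro-F1 snapshots are logged in
        ``history_``.
        """
        from .metrics import evaluate  # local import avoids a cycle

        docs = list(X)
        if not docs:
            raise ValueError("training corpus is empty")
        self._validate_hyperparams()
        self._build(docs, scheme=None)
        tensors = self._tensors()
        opt = (_Adam if self.optimizer == "adam" else _SGD)(
            tensors, self.learning_rate
        )
        rng = np.random.default_rng(self.seed)
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(docs))
            epoch_ner, epoch_re, n_batches = 0.0, 0.0, 0
            for lo in range(0, len(docs), self.batch_size):
                batch = [docs[i] for i in order[lo: lo + self.batch_size]]
                opt.zero_grad()
                ner_sum, re_sum = Tensor(0.0), Tensor(0.0)
                for doc in batch:
                    ner, re = self._doc_losses(doc)
                    ner_sum = ner_sum + ner
                    re_sum = re_sum + re
                scale = 1.0 / len(batch)
                loss = (ner_sum + re_sum) * scale
                loss.backward()
                opt.step()
                epoch_ner += ner_sum.item() * scale
                epoch_re += re_sum.item() * scale
                n_batches += 1
            components = joint_loss(epoch_ner / n_batches, epoch_re / n_batches)
            record = {
                "epoch": epoch,
                "loss_ner": components.loss_ner,
                "loss_re": components.loss_re,
                "loss": components.loss,
            }
            if eval_docs is not None:
                preds = self.predict([d.tokens for d in eval_docs])
                report = evaluate(list(eval_docs), preds)
                record["ner_f1"] = report["ner"]["micro"]["f1"]
                record["re_f1"] = report["re"]["micro"]["f1"]
            self.history_.append(record)
        return self

    def predict(self, X) -> list[AnnotatedDocument]:
        """End-to-end prediction for a list of token sequences."""
        if not hasattr(self, "encoder_params_"):
            raise RuntimeError("predict() called before fit() or load()")
        return [self._predict_one(tokens) for tokens in X]

    def _predict_one(self, tokens) -> AnnotatedDocument:
        tokens = tuple(tokens)
        if not tokens:
            raise ValueError("cannot predict on an empty token sequence")
        Y = enc_mod.encode(self._ids(tokens), self.config_, self.encoder_params_)
        if self.ner_loss == "crf":
            emissions = crf_mod.ner_emissions(Y, self.crf_params_)
            tag_ids, _ = crf_mod.viterbi_decode(
                emissions, self.crf_params_.transitions
            )
        else:
            W, b = self.softmax_ner_params_
            posteriors = crf_mod.softmax_ner(Y, W, b)
            tag_ids = list(posteriors.data.argmax(axis=1))
        tags = [self.scheme_.bio_tags[i] for i in tag_ids]
        entities = bio_to_spans(tags, self.scheme_)
        pairs = re_mod.enumerate_candidate_pairs(entities)
        relations = []
        if pairs:
            vectors = [
                re_mod.pair_representation(Y, pair, self.re_params_)
                for pair in pairs
            ]
            scores = re_mod.relation_scores(vectors, self.re_params_)
            relations = re_mod.decode_relations(
                scores, pairs, self.scheme_,
                strategy=self.re_strategy, tau=self.tau,
            )
        return AnnotatedDocument(
            tokens=tokens, entities=entities, relations=tuple(relations)
        )

    # -- checkpointing ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialize config, vocabulary, label scheme and all tensors (JSON)."""
        layers = []
        for layer in self.encoder_params_.layers:
            layers.append({
                "W_Q": [t.data.tolist() for t in layer.attention.W_Q],
                "W_K": [t.data.tolist() for t in layer.attention.W_K],
                "W_V": [t.data.tolist() for t in layer.attention.W_V],
                "W_O": layer.attention.W_O.data.tolist(),
                "ln1_G": layer.ln1.G.data.tolist(),
                "ln1_B": layer.ln1.B.data.tolist(),
                "ffn_W1": layer.ffn.W1.data.tolist(),
                "ffn_b1": layer.ffn.b1.data.tolist(),
                "ffn_W2": layer.ffn.W2.data.tolist(),
                "ffn_b2": layer.ffn.b2.data.tolist(),
                "ln2_G": layer.ln2.G.data.tolist(),
                "ln2_B": layer.ln2.B.data.tolist(),
            })
        payload = {
            "params": self.get_params(),
            "vocab": self.vocab_,
            "scheme": self.scheme_.to_dict(),
            "encoder_config": self.config_.to_dict(),
            "token_embedding": self.encoder_params_.token_embedding.data.tolist(),
            "position_embedding": self.encoder_params_.position_embedding.data.tolist(),
            "layers": layers,
            "crf": {
                "W_E": self.crf_params_.W_E.data.tolist(),
                "b_E": self.crf_params_.b_E.data.tolist(),
                "transitions": self.crf_params_.transitions.data.tolist(),
            },
            "softmax_ner": [t.data.tolist() for t in self.softmax_ner_params_],
            "re": {
                "W_B": self.re_params_.W_B.data.tolist(),
                "W_R": self.re_params_.W_R.data.tolist(),
                "b_R": self.re_params_.b_R.data.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "JointExtractor":
        """Restore a checkpoint; predictions are bit-identical to the saver's."""
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        model = cls(**payload["params"])
        model.vocab_ = dict(payload["vocab"])
        model.scheme_ = LabelScheme.from_dict(payload["scheme"])
        model.config_ = enc_mod.EncoderConfig.from_dict(payload["encoder_config"])

        def t(data):
            return Tensor(np.array(data, dtype=np.float64), requires_grad=True)

        model.encoder_params_ = enc_mod.EncoderParams(
            token_embedding=t(payload["token_embedding"]),
            position_embedding=t(payload["position_embedding"]),
        )
        for ldata in payload["layers"]:
            model.encoder_params_.layers.append(
                enc_mod.EncoderLayerParams(
                    attention=enc_mod.AttentionParams(
                        W_Q=[t(w) for w in ldata["W_Q"]],
                        W_K=[t(w) for w in ldata["W_K"]],
                        W_V=[t(w) for w in ldata["W_V"]],
                        W_O=t(ldata["W_O"]),
                    ),
                    ln1=enc_mod.LayerNormParams(
                        G=t(ldata["ln1_G"]), B=t(ldata["ln1_B"]),
                        eps=model.config_.eps,
                    ),
                    ffn=enc_mod.FfnParams(
                        W1=t(ldata["ffn_W1"]), b1=t(ldata["ffn_b1"]),
                        W2=t(ldata["ffn_W2"]), b2=t(ldata["ffn_b2"]),
                    ),
                    ln2=enc_mod.LayerNormParams(
                        G=t(ldata["ln2_G"]), B=t(ldata["ln2_B"]),
                        eps=model.config_.eps,
                    ),
                )
            )
        model.crf_params_ = crf_mod.CrfParameters(
            W_E=t(payload["crf"]["W_E"]),
            b_E=t(payload["crf"]["b_E"]),
            transitions=t(payload["crf"]["transitions"]),
        )
        model.softmax_ner_params_ = tuple(t(w) for w in payload["softmax_ner"])
        model.re_params_ = re_mod.ReParameters(
            W_B=t(payload["re"]["W_B"]),
            W_R=t(payload["re"]["W_R"]),
            b_R=t(payload["re"]["b_R"]),
        )
        model.history_ = []
        return model
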