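"""Seeded synthetic clinical corpora with exact gold annotations.

Documents are assembled from subject–verb–object clause skeletons whose
slots are filled with entity surface forms, e.g.::

    metformin given 500 mg        -> DRUG --DRUG_DOSE--> DOSE
    ecg showed abnormal           -> TEST --TEST_RESULT--> RESULT

Each configured relation rule (head type, tail type, label, probability)
independently instantiates such a clause with its stated probability, so
the empirical per-document frequency of a relation converges to the
rule's probability. Standalone entity mentions (no relation) and filler
tokens from a background vocabulary are mixed in; with probability
``noise_rate`` a filler position draws from a distractor list of
entity-lookalike tokens instead (surface forms that resemble drug or
dose mentions morphologically but are never annotated).

The generator is the package's stand-in for access-restricted clinical
corpora: entity/relation inventories mirror medication-event annotation
(drugs, doses, diseases, symptoms, tests, results; drug–dose,
drug–indication, drug–adverse-event, test–result links). Ground truth is
exact by construction. Documents are generated with a per-document
random stream derived from (seed, doc index), so corpora are
prefix-consistent: growing ``n_docs`` with a fixed seed extends the
corpus without changing earlier documents.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import AnnotatedDocument, EntitySpan, LabelScheme, RelationInstance

__all__ = [
    "GeneratorConfig",
    "RelationRule",
    "generate_corpus",
    "summarize_corpus",
    "default_scheme",
]


@dataclass(frozen=True)
class RelationRule:
    head_type: str
    tail_type: str
    label: str
    probability: float

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"rule {self.label!r}: probability outside [0, 1]")


DEFAULT_INVENTORIES: dict[str, tuple[tuple[str, ...], ...]] = {
    "DRUG": (
        ("aspirin",), ("metformin",), ("lisinopril",), ("ibuprofen",),
        ("warfarin",), ("amoxicillin",), ("atorvastatin",), ("omeprazole",),
    ),
    "DOSE": (
        ("100", "mg"), ("250", "mg"), ("500", "mg"), ("10", "mg"),
        ("5", "ml"), ("2", "tablets"),
    ),
    "DISEASE": (
        ("hypertension",), ("diabetes",), ("pneumonia",), ("asthma",),
        ("arthritis",), ("heart", "disease"),
    ),
    "SYMPTOM": (
        ("rash",), ("nausea",), ("headache",), ("dizziness",),
        ("fatigue",), ("cough",),
    ),
    "TEST": (
        ("blood", "pressure"), ("glucose",), ("ecg",), ("xray",),
        ("heart", "rate"),
    ),
    "RESULT": (
        ("elevated",), ("normal",), ("abnormal",), ("low",), ("high",),
    ),
}

DEFAULT_RULES: tuple[RelationRule, ...] = (
    RelationRule("DRUG", "DOSE", "DRUG_DOSE", 0.8),
    RelationRule("DRUG", "DISEASE", "DRUG_INDICATION", 0.6),
    RelationRule("DRUG", "SYMPTOM", "DRUG_ADVERSE", 0.5),
    RelationRule("TEST", "RESULT", "TEST_RESULT", 0.7),
)

# Connector verb per relation label; unlisted labels fall back to the
# lowercased label so arbitrary rules still produce valid clauses.
RELATION_VERBS = {
    "DRUG_DOSE": "given",
    "DRUG_INDICATION": "treats",
    "DRUG_ADVERSE": "caused",
    "TEST_RESULT": "showed",
}

DEFAULT_VOCAB: tuple[str, ...] = (
    "patient", "the", "was", "admitted", "with", "stable", "condition",
    "on", "exam", "today", "continued", "daily", "noted", "review",
    "followup", "chart", "states", "and", "plan", "home", "discharged",
    "morning", "evening", "clinic", "visit", "course", "tolerated",
    "well", "denies", "reports",
)

# Entity-lookalike distractors; morphologically drug/dose-like but never
# annotated, so token identity alone still determines entity status.
DEFAULT_DISTRACTORS: tuple[str, ...] = (
    "aspirinol", "metforal", "dosepak", "tabletine", "mgx",
    "glucorin", "cardizol", "pressurex",
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 375
    seed: int = 0
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    inventories: dict[str, tuple[tuple[str, ...], ...]] = field(
        default_factory=lambda: dict(DEFAULT_INVENTORIES)
    )
    relation_rules: tuple[RelationRule, ...] = DEFAULT_RULES
    doc_len_range: tuple[int, int] = (10, 18)
    entity_density: float = 0.8  # expected standalone (relation-free) mentions
    noise_rate: float = 0.1
    distractors: tuple[str, ...] = DEFAULT_DISTRACTORS

    def __post_init__(self):
        if self.n_docs < 0:
            raise ValueError("n_docs must be nonnegative")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate outside [0, 1]")
        if self.entity_density < 0:
            raise ValueError("entity_density must be nonnegative")
        lo, hi = self.doc_len_range
        if not (1 <= lo <= hi):
            raise ValueError("doc_len_range must satisfy 1 <= min <= max")
        if not self.vocab:
            raise ValueError("background vocabulary is empty")
        referenced = {r.head_type for r in self.relation_rules} | {
            r.tail_type for r in self.relation_rules
        }
        for etype in referenced:
            if not self.inventories.get(etype):
                raise ValueError(
                    f"relation rules reference entity type {etype!r} with an "
                    "empty surface-form inventory"
                )

    def scheme(self) -> LabelScheme:
        return LabelScheme(
            entity_types=tuple(sorted(self.inventories)),
            relation_types=tuple(sorted({r.label for r in self.relation_rules})),
        )


def default_scheme() -> LabelScheme:
    return GeneratorConfig().scheme()


def _pick_surface(rng, config, etype) -> tuple[str, ...]:
    forms = config.inventories[etype]
    return forms[int(rng.integers(len(forms)))]


def _filler(rng, config) -> str:
    if config.noise_rate > 0 and rng.random() < config.noise_rate and config.distractors:
        return config.distractors[int(rng.integers(len(config.distractors)))]
    return config.vocab[int(rng.integers(len(config.vocab)))]


def _generate_document(rng: np.random.Generator, config: GeneratorConfig) -> AnnotatedDocument:
    # A clause is (tokens, [(offset, length, etype), ...], relation label or None).
    clauses: list[tuple[list[str], list[tuple[int, int, str]], str | None]] = []
    for rule in config.relation_rules:
        if rng.random() >= rule.probability:
            continue
        head = _pick_surface(rng, config, rule.head_type)
        tail = _pick_surface(rng, config, rule.tail_type)
        verb = RELATION_VERBS.get(rule.label, rule.label.lower())
        tokens = list(head) + [verb] + list(tail)
        ents = [
            (0, len(head), rule.head_type),
            (len(head) + 1, len(tail), rule.tail_type),
        ]
        clauses.append((tokens, ents, rule.label))
    # Standalone relation-free mentions keep NER from reducing to
    # relation-slot detection.
    for _ in range(int(rng.poisson(config.entity_density))):
        etype = sorted(config.inventories)[int(rng.integers(len(config.inventories)))]
        surface = _pick_surface(rng, config, etype)
        clauses.append((["noted"] + list(surface), [(1, len(surface), etype)], None))

    order = rng.permutation(len(clauses)) if clauses else []
    lo, hi = config.doc_len_range
    target_len = int(rng.integers(lo, hi + 1))
    clause_tokens = sum(len(clauses[i][0]) for i in order)
    n_fillers = max(target_len - clause_tokens, 0 if clauses else 1)
    # Distribute fillers across the len(clauses)+1 gaps.
    gap_counts = [0] * (len(clauses) + 1)
    for _ in range(n_fillers):
        gap_counts[int(rng.integers(len(gap_counts)))] += 1

    tokens: list[str] = []
    entities: list[EntitySpan] = []
    relations: list[RelationInstance] = []
    for gap, clause_idx in zip(gap_counts, list(order) + [None]):
        tokens.extend(_filler(rng, config) for _ in range(gap))
        if clause_idx is None:
            break
        ctokens, ents, rel_label = clauses[clause_idx]
        offset = len(tokens)
        tokens.extend(ctokens)
        ids = []
        for rel_start, length, etype in ents:
            eid = f"T{len(entities)}"
            entities.append(
                EntitySpan(
                    start=offset + rel_start,
                    end=offset + rel_start + length,
                    label=etype,
                    id=eid,
                )
            )
            ids.append(eid)
        if rel_label is not None:
            relations.append(
                RelationInstance(head=ids[0], tail=ids[1], label=rel_label)
            )
    return AnnotatedDocument(
        tokens=tuple(tokens), entities=tuple(entities), relations=tuple(relations)
    )


def generate_corpus(config: GeneratorConfig | None = None) -> list[AnnotatedDocument]:
    """Generate ``config.n_docs`` annotated documents, deterministically."""
    config = config or GeneratorConfig()
    docs = []
    for i in range(config.n_docs):
        rng = np.random.default_rng([config.seed, i])
        docs.append(_generate_document(rng, config))
    return docs


def summarize_corpus(docs: Sequence[AnnotatedDocument]) -> dict:
    """Exact per-type entity counts, per-label relation counts, token count."""
    entity_counts: Counter[str] = Counter()
    relation_counts: Counter[str] = Counter()
    n_tokens = 0
    for doc in docs:
        n_tokens += len(doc.tokens)
        entity_counts.update(e.label for e in doc.entities)
        relation_counts.update(r.label for r in doc.relations)
    return {
        "n_docs": len(docs),
        "n_tokens": n_tokens,
        "entities": dict(sorted(entity_counts.items())),
        "relations": dict(sorted(relation_counts.items())),
    }
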