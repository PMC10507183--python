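"""Annotated-corpus data model and I/O.

The unit of everything downstream — training, prediction, evaluation — is
the :class:`AnnotatedDocument`: a token sequence plus typed entity spans
and typed, directed relations between them. Spans use 0-based, half-open
``[start, end)`` token coordinates. Entities must be pairwise
non-overlapping because the tagger encodes them as a per-token BIO
sequence, which cannot represent nesting.

Two serialization dialects are supported:

* JSONL — one document per line, lossless (tokens, entities, relations);
* CoNLL-style TSV — one ``TOKEN<TAB>BIO-TAG`` line per token, blank line
  between documents. Relations are not representable and are dropped on
  write / empty on read, by contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EntitySpan",
    "RelationInstance",
    "AnnotatedDocument",
    "LabelScheme",
    "CorpusValidationError",
    "read_documents",
    "write_documents",
    "spans_to_bio",
    "bio_to_spans",
]


class CorpusValidationError(ValueError):
    """An annotation violates a document invariant."""


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity occupying tokens ``[start, end)``."""

    start: int
    end: int
    label: str
    id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(
                f"entity {self.id!r}: invalid span [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class RelationInstance:
    """A directed, typed relation between two entity ids (head -> tail)."""

    head: str
    tail: str
    label: str

    def __post_init__(self):
        if self.head == self.tail:
            raise CorpusValidationError(
                f"relation {self.label!r}: head and tail are both {self.head!r}"
            )


@dataclass(frozen=True)
class AnnotatedDocument:
    tokens: tuple[str, ...]
    entities: tuple[EntitySpan, ...] = ()
    relations: tuple[RelationInstance, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "entities", tuple(self.entities))
        object.__setattr__(self, "relations", tuple(self.relations))
        self._validate()

    def _validate(self) -> None:
        if not self.tokens:
            raise CorpusValidationError("document has no tokens")
        n = len(self.tokens)
        ids = set()
        occupied = [False] * n
        for ent in self.entities:
            if ent.end > n:
                raise CorpusValidationError(
                    f"entity {ent.id!r} span [{ent.start}, {ent.end}) exceeds "
                    f"document length {n}"
                )
            if ent.id in ids:
                raise CorpusValidationError(f"duplicate entity id {ent.id!r}")
            ids.add(ent.id)
            for i in range(ent.start, ent.end):
                if occupied[i]:
                    raise CorpusValidationError(
                        f"entity {ent.id!r} overlaps another entity at token {i}"
                    )
                occupied[i] = True
        for rel in self.relations:
            for endpoint in (rel.head, rel.tail):
                if endpoint not in ids:
                    raise CorpusValidationError(
                        f"relation {rel.label!r} references unknown entity "
                        f"id {endpoint!r}"
                    )

    def entity_by_id(self, entity_id: str) -> EntitySpan:
        for ent in self.entities:
            if ent.id == entity_id:
                return ent
        raise KeyError(entity_id)


@dataclass(frozen=True)
class LabelScheme:
    """Fixed, ordered inventories of entity and relation types.

    ``bio_tags`` is derived as ``O`` plus ``B-X``/``I-X`` per entity type
    (size ``2*|E| + 1``); relation classes get a reserved ``NO_RELATION``
    null class appended, so the relation head scores ``|R| + 1`` classes.
    Tag and label order is fixed and serialized with trained models.
    """

    entity_types: tuple[str, ...]
    relation_types: tuple[str, ...]
    bio_tags: tuple[str, ...] = field(init=False)

    NO_RELATION = "NO_RELATION"

    def __post_init__(self):
        object.__setattr__(self, "entity_types", tuple(self.entity_types))
        object.__setattr__(self, "relation_types", tuple(self.relation_types))
        tags = ["O"]
        for etype in self.entity_types:
            tags.append(f"B-{etype}")
            tags.append(f"I-{etype}")
        object.__setattr__(self, "bio_tags", tuple(tags))

    @property
    def num_tags(self) -> int:
        return len(self.bio_tags)

    @property
    def num_relation_classes(self) -> int:
        """Substantive relation classes plus the null class."""
        return len(self.relation_types) + 1

    def tag_index(self, tag: str) -> int:
        try:
            return self.bio_tags.index(tag)
        except ValueError:
            raise KeyError(f"unknown BIO tag {tag!r}") from None

    def relation_index(self, label: str) -> int:
        """0 is reserved for NO_RELATION; substantive classes follow."""
        if label == self.NO_RELATION:
            return 0
        try:
            return self.relation_types.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown relation label {label!r}") from None

    def relation_label(self, index: int) -> str:
        if index == 0:
            return self.NO_RELATION
        return self.relation_types[index - 1]

    def to_dict(self) -> dict:
        return {
            "entity_types": list(self.entity_types),
            "relation_types": list(self.relation_types),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LabelScheme":
        return cls(
            entity_types=tuple(payload["entity_types"]),
            relation_types=tuple(payload["relation_types"]),
        )


# ---------------------------------------------------------------------------
# JSONL / CoNLL serialization
# ---------------------------------------------------------------------------


def _doc_to_json(doc: AnnotatedDocument) -> dict:
    return {
        "tokens": list(doc.tokens),
        "entities": [
            {"id": e.id, "start": e.start, "end": e.end, "label": e.label}
            for e in doc.entities
        ],
        "relations": [
            {"head": r.head, "tail": r.tail, "label": r.label}
            for r in doc.relations
        ],
    }


def _doc_from_json(payload: dict) -> AnnotatedDocument:
    entities = tuple(
        EntitySpan(start=e["start"], end=e["end"], label=e["label"], id=e["id"])
        for e in payload.get("entities", [])
    )
    relations = tuple(
        RelationInstance(head=r["head"], tail=r["tail"], label=r["label"])
        for r in payload.get("relations", [])
    )
    return AnnotatedDocument(
        tokens=tuple(payload["tokens"]), entities=entities, relations=relations
    )


def read_documents(path, format: str = "jsonl") -> list[AnnotatedDocument]:
    """Read an annotated corpus.

    JSONL input is lossless; CoNLL input decodes BIO tags into entity
    spans (ill-formed sequences repaired deterministically) and yields
    empty relation lists. Malformed records raise a parse error naming
    the offending line.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if format == "jsonl":
        docs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                payload = json.loads(line)
                docs.append(_doc_from_json(payload))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}")
        return docs
    if format == "conll":
        return _read_conll(text, path)
    raise ValueError(f"unknown corpus format {format!r}")


def _read_conll(text: str, path) -> list[AnnotatedDocument]:
    docs: list[AnnotatedDocument] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush():
        if tokens:
            spans = _decode_bio(list(tags))
            docs.append(AnnotatedDocument(tokens=tuple(tokens), entities=spans))
            tokens.clear()
            tags.clear()

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected TOKEN<TAB>TAG, got {line!r}"
            )
        tokens.append(parts[0])
        tags.append(parts[1])
    flush()
    return docs


def write_documents(
    docs: Sequence[AnnotatedDocument], path, format: str = "jsonl"
) -> None:
    """Write a corpus; jsonl round-trips exactly, conll drops relations."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for doc in docs:
                fh.write(json.dumps(_doc_to_json(doc), ensure_ascii=False))
                fh.write("\n")
        return
    if format == "conll":
        scheme = None  # tags are written from span labels directly
        lines: list[str] = []
        for doc in docs:
            tags = _encode_bio(doc)
            lines.extend(f"{tok}\t{tag}" for tok, tag in zip(doc.tokens, tags))
            lines.append("")
        path.write_text("\n".join(lines), encoding="utf-8")
        return
    raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# BIO encoding / decoding
# ---------------------------------------------------------------------------


def _encode_bio(doc: AnnotatedDocument) -> list[str]:
    tags = ["O"] * len(doc.tokens)
    for ent in doc.entities:
        tags[ent.start] = f"B-{ent.label}"
        for i in range(ent.start + 1, ent.end):
            tags[i] = f"I-{ent.label}"
    return tags


def spans_to_bio(doc: AnnotatedDocument, scheme: LabelScheme) -> list[str]:
    """Encode a document's entity spans as a BIO tag sequence."""
    for ent in doc.entities:
        if ent.label not in scheme.entity_types:
            raise KeyError(f"entity type {ent.label!r} not in scheme")
    return _encode_bio(doc)


def _decode_bio(tags: list[str]) -> tuple[EntitySpan, ...]:
    """Decode BIO tags into spans, repairing ill-formed sequences.

    Repair rule (deterministic, idempotent): ``I-X`` without a preceding
    ``B-X``/``I-X`` of the same type opens a new span, i.e. acts as
    ``B-X``.
    """
    spans: list[EntitySpan] = []
    start = None
    label = None

    def close(end: int) -> None:
        nonlocal start, label
        if start is not None:
            spans.append(
                EntitySpan(start=start, end=end, label=label, id=f"T{len(spans)}")
            )
            start, label = None, None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i)
        elif tag.startswith("B-"):
            close(i)
            start, label = i, tag[2:]
        elif tag.startswith("I-"):
            if label != tag[2:]:
                close(i)  # type switch or I-after-O: open a fresh span
                start, label = i, tag[2:]
        else:
            raise KeyError(f"unknown BIO tag {tag!r}")
    close(len(tags))
    return tuple(spans)


def bio_to_spans(
    tags: Iterable[str], scheme: LabelScheme | None = None
) -> tuple[EntitySpan, ...]:
    """Decode a BIO tag sequence into entity spans (inverse of spans_to_bio)."""
    tags = list(tags)
    if scheme is not None:
        for tag in tags:
            if tag not in scheme.bio_tags:
                raise KeyError(f"unknown BIO tag {tag!r}")
    return _decode_bio(tags)
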