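import numpy as np
import pytest

from emrjoint.corpus import AnnotatedDocument, EntitySpan, LabelScheme, RelationInstance


@pytest.fixture
def scheme() -> LabelScheme:
    return LabelScheme(
        entity_types=("DISEASE", "DOSE", "DRUG"),
        relation_types=("DRUG_DOSE", "DRUG_INDICATION"),
    )


def make_random_document(
    rng: np.random.Generator,
    scheme: LabelScheme,
    max_len: int = 20,
    with_relations: bool = False,
) -> AnnotatedDocument:
    """A random valid document: tokens, non-overlapping typed spans,
    optionally relations between random entity pairs."""
    n = int(rng.integers(1, max_len + 1))
    tokens = tuple(f"w{int(rng.integers(50))}" for _ in range(n))
    entities = []
    pos = 0
    while pos < n:
        if rng.random() < 0.4:
            length = int(rng.integers(1, min(3, n - pos) + 1))
            label = scheme.entity_types[int(rng.integers(len(scheme.entity_types)))]
            entities.append(
                EntitySpan(start=pos, end=pos + length, label=label,
                           id=f"T{len(entities)}")
            )
            pos += length
        else:
            pos += 1
    relations = []
    if with_relations and len(entities) >= 2:
        k = int(rng.integers(0, len(entities)))
        seen = set()
        for _ in range(k):
            i, j = rng.choice(len(entities), size=2, replace=False)
            if (i, j) in seen:
                continue
            seen.add((i, j))
            label = scheme.relation_types[
                int(rng.integers(len(scheme.relation_types)))
            ]
            relations.append(
                RelationInstance(
                    head=entities[int(i)].id, tail=entities[int(j)].id, label=label
                )
            )
    return AnnotatedDocument(
        tokens=tokens, entities=tuple(entities), relations=tuple(relations)
    )
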