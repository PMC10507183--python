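# Methods

`emrjoint` implements a joint model for named entity recognition (NER) and
relation extraction (RE) over clinical-style text: one transformer encoder
feeds two task heads, and both are trained together by minimizing the sum of
the two task losses. This note records the model definition, the assumptions
baked into the implementation, the synthetic data generator and its limits,
and the numerical choices that matter for reproducing results.

## Model

### Input and encoder

A document is a sequence of `n` pre-tokenized tokens. Each token id is mapped
to a learned embedding of size `h`, and a learned absolute position embedding
of size `h` is added, giving `X ∈ R^{n×h}`. The encoder is a stack of `L`
post-norm transformer layers. Layer `l` computes

    U = LayerNorm(X + MultiHead(X))
    Y = LayerNorm(U + FFN(U))

where:

- **Scaled dot-product attention** for one head with parameters
  `W_Q, W_K, W_V ∈ R^{h×d_k}`:
  `Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V` with `Q = X W_Q` etc.
- **Multi-head attention** concatenates `m` heads (`d_k = d_v = h/m`) and
  projects with `W_O ∈ R^{h×h}`.
- **FFN** is a two-layer ReLU network with inner width `d`:
  `FFN(u) = W_2 max(0, W_1 u + b_1) + b_2`.
- **LayerNorm** standardizes each position's vector to mean 0 / variance 1
  (with stabilizer `eps`) and applies a learned per-coordinate affine map.

No dropout is used: the package targets deterministic, verifiable small-scale
training, not large-scale regularization.

### NER head: linear-chain CRF

Encoder outputs are projected to per-token emission scores over the BIO tag
set (`c = 2·|entity types| + 1` tags). A linear-chain CRF with transition
matrix `A` (augmented with explicit START and STOP states) defines

    score(y | x) = A[START, y_1] + Σ_t E[t, y_t] + Σ_t A[y_{t-1}, y_t] + A[y_n, STOP]
    log p(y | x) = score(y | x) − log Z(x)

`log Z` is computed by the forward algorithm in log space (logsumexp
recursion); decoding uses Viterbi with first-argmax (lowest tag index)
tie-breaking. By default a structural BIO mask forbids transitions into
`I-X` from anything other than `B-X`/`I-X`, so decoded sequences are always
valid BIO. An independent per-token softmax classifier is available as an
alternative (`ner_loss="softmax"`).

### RE head: bilinear attention over span pairs

For every ordered pair of entity spans (head, tail), the head gathers the
encoder rows of each span, `U_head ∈ R^{p×h}` and `U_tail ∈ R^{q×h}`, and
computes a bilinear compatibility matrix `S = U_head W_B U_tail^T`. Each span
is pooled with a softmax over its maximum compatibility with the other span:

    a = softmax_i(max_j S[i, j]),  e_head = Σ_i a_i U_head[i]
    b = softmax_j(max_i S[i, j]),  e_tail = Σ_j b_j U_tail[j]

The pair representation is the concatenation `[e_head; e_tail] ∈ R^{2h}`,
scored linearly against `r` classes (the relation types plus a reserved
NO_RELATION class at index 0). Decoding is per-pair argmax (a relation is
emitted unless the null class wins), or a probability threshold `tau` on the
best non-null class. Single-token spans make the pooling reduce exactly to
concatenation of the two token vectors; `W_B = 0` reduces it to mean pooling.

### Joint training

    Loss = Loss_ner + Loss_re            (unweighted 1:1 sum)

- `Loss_ner` is the CRF negative log-likelihood, normalized per token so the
  two components have comparable magnitude.
- `Loss_re` is the mean cross-entropy over candidate pairs, using **gold**
  entity spans during training (teacher forcing); every ordered gold pair not
  labeled with a relation is a NO_RELATION example.
- At prediction time the pipeline is fully end-to-end: encode → Viterbi →
  BIO-to-spans → candidate pairs from *predicted* spans → relation decoding.

Optimization is Adam (default, lr 1e-3) or plain SGD over minibatches of
documents; each document in a batch is processed individually and the batch
loss is the mean of per-document losses (mathematically identical to the
padded-and-masked batch formulation, and simpler).

## Assumptions

- Input text is pre-tokenized; the package never splits strings.
- Entity spans are contiguous token intervals and do not overlap; relations
  are ordered (head, tail) pairs of annotated entities. These invariants are
  validated on construction of every `AnnotatedDocument`.
- Unknown tokens at prediction time map to a reserved `<UNK>` id (index 0).
- Sequences are bounded by `max_n` (default 128); longer inputs are an error
  rather than silently truncated.
- Candidate pair enumeration is capped at 200 ordered pairs per document
  (deterministic truncation) to bound the quadratic pair cost.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `L` | 2 | encoder layers |
| `h` | 64 | hidden size (embeddings, attention, heads) |
| `m` | 4 | attention heads (`h % m == 0`) |
| `d` | 128 | FFN inner width |
| `max_n` | 128 | maximum sequence length |
| `eps` | 1e-5 | layer-norm stabilizer |
| `epochs` | 30 | training epochs |
| `batch_size` | 8 | documents per minibatch |
| `learning_rate` | 1e-3 | Adam/SGD step size |
| `optimizer` | `"adam"` | `"adam"` or `"sgd"` |
| `ner_loss` | `"crf"` | `"crf"` or `"softmax"` |
| `re_strategy` | `"argmax"` | `"argmax"` or `"threshold"` |
| `tau` | 0.5 | threshold for `re_strategy="threshold"` |
| `task` | `"joint"` | `"joint"`, `"ner"` or `"re"` (ablations) |
| `bio_mask` | `True` | structural CRF transition mask |
| `seed` | 0 | root seed (init + shuffling) |

All weights are initialized uniformly in `±1/sqrt(fan_in)` from seeded
`numpy.random.default_rng` streams; biases start at zero.

## Synthetic data generator

Real clinical corpora are access-restricted, so the package ships a seeded
template generator (`emrjoint.synthetic`). A document is built from:

- **Relation clauses**: each relation rule (e.g. DRUG→DOSE with probability
  0.8) independently fires per document; a firing rule contributes a clause
  `<head surface> <verb> <tail surface>` (verbs: *given*, *treats*, *caused*,
  *showed*) and the corresponding gold relation.
- **Standalone mentions**: `noted <entity>` clauses with Poisson-distributed
  count (rate `entity_density`), contributing entities without relations.
- **Filler and distractor tokens**: background vocabulary plus lookalike
  non-entities (e.g. "aspirinol"), distributed between clauses at rate
  `noise_rate`, padding documents to a sampled target length.

Entity surfaces include multi-token forms, so both B and I tags occur.
Per-document RNG is `default_rng([seed, i])`: corpora are deterministic and
prefix-consistent (growing `n_docs` extends, never rewrites, the corpus).

### Limitations

- Relations are deterministic given the text (the verb identifies the
  relation), so the generator measures whether the architecture can learn
  compositional patterns, not robustness to genuine ambiguity.
- Vocabulary is tiny (~100 types) and grammar is fixed SVO clauses; there is
  no morphology, negation, coreference, or cross-sentence structure.
- Entities never overlap and never nest, matching the model's assumptions by
  construction; the generator cannot probe behavior outside them.
- Class balance is controlled only indirectly through rule probabilities.

## Numerical choices

- All computation is float64 NumPy; gradients come from a small tape-based
  reverse-mode autodiff engine (`emrjoint.autodiff`), verified against
  central finite differences at 1e-4 relative tolerance.
- Forbidden CRF transitions use the finite sentinel `-1e30` rather than
  `-inf`, so log-space recursions never produce NaN; masked entries receive
  exactly zero gradient and are never updated.
- `logsumexp`/`softmax` subtract the running maximum before exponentiation.
- Determinism: every random choice (init, shuffling, generation) flows from
  explicit seeds; on a single thread, repeated runs are bit-identical, and
  saved checkpoints (JSON, full float64 precision via repr round-trip)
  restore bit-identical predictions.
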