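# Methods

## Pipeline model and assumptions

`phenorag` treats HPO annotation as retrieval-constrained selection. The
central assumption is that a language model is good at *reading* (finding
phenotype descriptions in prose, handling negation and family history in
context) but cannot be trusted to *cite* (produce valid ontology ids).
The pipeline therefore splits the task: the model proposes surface
phrases; the knowledge base and vector index propose identifiers; the
model only ever chooses among identifiers the retrieval layer supplied.
The emitted id set is a subset of the knowledge base by construction,
which converts hallucination from a statistical tendency into a
structural impossibility (measured here as 0 invalid ids over 1,000
adversarial assignment replies).

## Knowledge base

Phrases are drawn from term labels, synonyms, definitions and comments of
a parsed HPO release (OBO or OBO-Graphs JSON dialect, both via standard
parsers). Normalization is deliberately minimal — lower-casing,
whitespace collapse, surrounding-punctuation strip, no stemming — so the
exact-match path stays auditable: a direct hit means the note literally
contains a knowledge-base phrase. Duplicate (phrase, term) pairs collapse
keeping the highest-priority source (label > synonym > definition >
comment > custom). Definitions and comments are included by default but
carry their source tag so callers can exclude or down-weight them.

Each entry stores a display lineage: the root-to-term chain choosing the
lexicographically smallest parent at multi-parent steps. This canonical
path is prompt metadata only; every correctness-relevant graph query
(`ancestors`, the FP taxonomy) uses the full parent DAG. The organ
system of an entry is the label of the depth-1 child of the
phenotypic-abnormality branch (`HP:0000118`) on the canonical path, empty
for terms outside that branch (e.g. inheritance modifiers).

User-supplied custom phrases merge with per-entry validation: unknown or
malformed ids are rejected with reasons (never silently dropped), and
phrases pointing at an obsolete term with a named replacement are
remapped to the replacement and flagged — retired-id drift is a known
failure mode of frozen dictionaries, and remapping removes it.

The KB `version` field records the ontology release tag only; a wall
clock timestamp is not baked into the serialized KB so that rebuilding
from the same release is bit-identical (idempotence is tested).

## Embeddings and retrieval

Similarity is cosine on L2-normalized vectors, realized as an inner
product. The index is exact: with tens of thousands of rows a full scan
is one matrix-vector product, so nothing approximate is needed and the
retrieval layer can be verified against a per-row brute-force oracle
(strict equality on 100 seeded queries, ties broken by ascending HPO id
then phrase to keep results platform-reproducible).

The embedding backend is a contract — any callable mapping strings to a
fixed-dimension matrix, deterministically — so a sentence-embedding
model can be plugged in where richer semantics are wanted. The default
`HashingEmbedder` is a seeded feature-hash projection of character
3–5-grams plus word tokens (keyed BLAKE2b hashing for bucket and sign,
then L2 normalization). It is fully deterministic, dependency-free, and
places surface-similar phrases near each other, which is the property
the cascade's last resort needs; it does not capture synonymy beyond
shared n-grams (see Limitations).

Defaults: dimension 256 (128 in tests), retrieval depth k = 20.

## Fuzzy matching

The fuzzy shortcut uses Levenshtein distance (edlib) normalized by the
longer string: `ratio = 1 − d/max(|a|, |b|)`; a single deletion between
"furowed tongue" and "furrowed tongue" scores 14/15 ≈ 0.933. The
auto-accept threshold defaults to 0.95, deliberately conservative: the
shortcut exists to absorb typos and trivial inflection, while genuinely
ambiguous phrases fall through to the candidate list where the model
decides with sentence context. Fuzzy hits are recorded with provenance
`fuzzy` and their ratio, so downstream audits can distinguish them from
exact and model-selected assignments.

## Prompts and the model contract

The two system prompts are reconstructed behavioral contracts, not
verbatim published prompts, and are configuration: both can be replaced
from plain-text files. The extraction prompt demands a JSON list of
verbatim phrases and excludes negated findings, family history,
administrative detail, and disease-name components; negation handling
lives entirely in the prompt — there is no separate assertion
classifier. The assignment prompt demands `{"id": ...}` from the
supplied candidate list (or `"none"`), preferring the most distal node.

Reply handling is strict JSON with bounded repair: a parse or schema
failure triggers up to `max_retries` re-prompts appending the schema and
the invalid output; the final failure returns a marker, never an
exception, so batch runs cannot stall. Assignment adds one dedicated
re-prompt when a syntactically valid id is not among the candidates; a
second violation falls back deterministically to the rank-1 candidate
and increments a diagnostic counter. The API key is read from an
environment variable at call time and never enters logs or error
messages (tested by log capture).

The mock backend replays this contract from a phrase→id lexicon:
extraction returns lexicon phrases found verbatim (case-insensitive),
assignment returns the highest-similarity candidate matching the lexicon
target, else rank 1. It detects the phase from the request payload shape
(assignment requests are JSON objects with a `candidates` key), so it
keeps working when prompts are overridden.

## Evaluation conventions

Scoring is exact-id set matching per case: TP = predicted ∩ standard,
FP = predicted \ standard, FN = standard \ predicted, duplicates
collapsed first. Cases with fewer than 3 standard terms are excluded by
default. Metrics are reported in both conventions, explicitly labeled,
because they genuinely differ on uneven cases: pooled (micro — sum
counts, then ratio) and per-case mean (macro — per-case ratios, then
mean, excluding cases where a ratio is undefined). Undefined ratios are
reported as explicit nulls, never NaN.

False positives are classified against the case's standard terms:

- **direct_ancestor** — the FP lies on one ancestry path with a target,
  in either direction; the sub-direction (broader vs narrower) is
  reported separately, since a broader term is still clinically
  informative;
- **indirect_relative** — the FP and a target share an ancestor strictly
  below the phenotypic-abnormality entry point (sharing only
  `HP:0000118` or the root does not count);
- **unrelated** — neither of the above, id exists;
- **hallucination** — id absent from the ontology.

The classifier is verified against an independent graph-reachability
oracle on every (FP, target) pair of the fixture ontology.

Tool comparison uses a paired two-sided t-test on per-case metric
values. Zero-variance difference vectors are reported explicitly
(identical vectors: p = 1; constant nonzero shift: p = 0) rather than
propagating NaN. Calibration is checked by simulation: type-I error at
α = 0.05 over 1,000 null replicates of 30 paired cases.

## Synthetic data

The fixture generator emulates the *shape* of a case-report benchmark:
a ~30-term mini-ontology (multi-organ phenotypic-abnormality branch, a
multi-parent term, an obsolete term with replacement, a non-phenotype
branch, and the specific ancestry fragments the worked example needs),
and synthetic notes of templated clinical sentences with 16 planted
findings per case — matching the benchmark cohort's mean terms per
case — sampled without replacement from label/synonym phrases of
organ-system terms. Phrases in a substring relation are never co-planted,
so every planted phrase occurs verbatim exactly once. Distractor
sentences (negations, family history) carry their own ids which must not
be recovered.

What passing on this data shows: the plumbing is lossless — verbatim KB
phrases are recovered with precision and recall 1.0 through the full
pipeline, retrieval equals its oracle, and invalid model output cannot
leak into results. What it does not show: performance on real clinical
prose, where phrases are paraphrased, the ontology has 17,000+ terms,
extraction quality depends on the attached language model, and embedding
quality depends on the plugged-in backend. Published cohort-level scores
are therefore reproduced here only at the formula level, from the
published count tables, not re-measured.

## Numerical and design choices

- Cosine ties break by ascending HPO id, then phrase; all sorts are
  stable and seeded, so mock-backend runs are byte-reproducible.
- Zero-norm embeddings (empty strings cannot occur post-normalization,
  but defensively) are given a unit basis vector instead of NaN.
- Temperature defaults to 0; with the mock backend the entire pipeline,
  including batch CSV bytes, is deterministic across runs.
- Batch output is RFC 4180 CSV, UTF-8, all cells quoted, `\r\n` line
  endings, JSON cell values with sorted keys — chosen so determinism is
  testable as byte equality.
- Problem sizes in the shipped checks: 100 retrieval-oracle queries,
  1,056 FP-taxonomy pairs (exhaustive over the fixture), 1,000
  adversarial assignments, 50 synthetic cases of 16 findings, 1,000
  t-test replicates. These run in seconds on one CPU.

## Known limitations

- The hashing embedder has no notion of synonymy beyond shared n-grams;
  production use should plug a sentence-embedding backend into the
  `EmbeddingBackend` contract.
- Whether near-miss fuzzy matches should bypass the model entirely is a
  judgment call; here they do (above 0.95), flagged in provenance. Lower
  thresholds route more phrases through the model at higher cost.
- Sentence segmentation is rule-based (`.!?;` with an abbreviation
  guard); clinical shorthand with unusual punctuation may yield imperfect
  context windows. The context sentence only feeds the assignment prompt,
  so segmentation errors cannot change exact/fuzzy results.
- Scoring is exact-id only; no information-content or lineage-weighted
  partial credit. The FP taxonomy is the instrument for "near miss"
  analysis instead.
- One model endpoint, sequential batch processing; no parallel dispatch.
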