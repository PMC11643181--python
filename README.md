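# phenorag

Retrieval-augmented Human Phenotype Ontology (HPO) annotation of free
clinical text.

Deep phenotyping — turning a clinical narrative into a set of HPO
identifiers (`HP:NNNNNNN`) — is a bottleneck in rare-disease genomics.
Dictionary-based concept recognizers miss paraphrased findings; bare
language models invent identifiers. `phenorag` combines the two: a
language model extracts candidate phenotypic phrases from the note, each
phrase is resolved against a phrase knowledge base built from an HPO
release, and the model's final term choice is *constrained to retrieved
candidates*, so an identifier that does not exist in the ontology cannot
be emitted.

The package is aimed at clinical-genomics researchers and tool builders
who want an auditable HPO annotation pipeline that works with any
OpenAI-compatible chat endpoint (or none at all — a deterministic mock
backend drives the full pipeline for testing and benchmarking).

## Method

For a note *t* the pipeline computes, per extracted phrase *p*:

1. **Extraction** — the model returns verbatim phrases describing patient
   phenotypic abnormalities, excluding negated findings, family history,
   and disease-name components; each phrase is located in *t* and paired
   with its containing sentence.
2. **Exact match** — if the normalized phrase equals a knowledge-base
   phrase, its HPO id is accepted directly.
3. **Fuzzy match** — else, if the best Levenshtein similarity
   `1 − d(p, q)/max(|p|, |q|)` over KB phrases *q* reaches the threshold
   (default 0.95), that entry is accepted.
4. **Semantic retrieval** — else *p* is embedded and the top *k* = 20
   KB entries by cosine similarity are retrieved (exact brute-force
   search); the model selects one candidate (or "none"), preferring the
   most distal (most specific) ontology node. An id outside the candidate
   list is re-prompted once, then replaced by the rank-1 candidate.

Evaluation against a manually annotated standard uses exact-id matching:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), reported
both pooled (micro) and as per-case means (macro). Each false positive is
classified by its relation to the standard terms: direct relative (same
ancestry path), indirect relative (shared ancestor inside the
phenotypic-abnormality branch), unrelated, or hallucination (id absent
from the ontology).

## Worked example

The bundled mini-ontology and the published sample case run end-to-end
without any model endpoint:

```python
from phenorag import fixtures, ontology, embedding, llm, annotate, evaluation

fixtures.make_mini_ontology(seed=0, path="mini.obo")
terms = ontology.parse_ontology("mini.obo")
kb = ontology.build_phrase_map(terms, version="mini")
embedder = embedding.HashingEmbedder(dim=128, seed=7)
index = embedding.build_index(embedding.embed_phrases(kb, embedder), kb)

we = fixtures.worked_example()
client = llm.LlmClient(llm.ModelConfig(), llm.MockBackend(we.phrase_lexicon))
result = annotate.Annotator(kb, index, client, embedder).annotate("sample", we.passage)
print(result.unique_terms)
record = evaluation.score_case(result.unique_terms, we.standard)
print(len(record.tp_terms), record.fp_terms, record.fn_terms)
```

prints

```
['HP:0000206', 'HP:0010742', 'HP:0003987', 'HP:0041081', 'HP:0000964', 'HP:0001328', 'HP:0001263', 'HP:0002821']
7 ['HP:0000206'] ['HP:0034417']
```

i.e. 8 phrases annotated, 7 HPO terms correct against the 8-term
standard; the one false positive (`HP:0000206`, glossitis, chosen for
"healed tongue lacerations" over the better-fitting `HP:0034417`) is an
*indirect relative* of the missed target — the two terms meet at
`HP:0000163` (abnormal oral cavity morphology):

```python
print(evaluation.categorize_fp("HP:0000206", we.standard, kb))  # indirect_relative
```

## Command line

```bash
phenorag build-kb hp.obo --custom extra_phrases.json -o kb.json
phenorag build-index kb.json -o index
phenorag annotate --input-csv notes.csv --id-column id \
    --kb kb.json --index index --config config.json -o annotated.csv
phenorag evaluate --predictions annotated.csv --standard standard.json \
    --kb kb.json -o metrics.json
```

`config.json` selects the backend (`openai` endpoint or `mock`),
retrieval depth `k`, the fuzzy threshold, and optional prompt-override
files. Batch output adds one `hpo_annotations` column of JSON to a copy
of the input CSV; runs with a deterministic backend are byte-identical
and interrupted runs restart with `--resume`.

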