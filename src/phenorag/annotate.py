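"""Two-phase annotation workflow: extract phrases, then assign HPO terms.

Phase 1 asks the model for verbatim phenotypic phrases and locates each
one in the note (first occurrence) together with its containing sentence.
Phase 2 resolves each phrase against the knowledge base through a hybrid
cascade: normalized exact match, then conservative fuzzy match, then
semantic top-k retrieval with final selection delegated to the model —
which may only choose from the retrieved candidates, so every emitted id
exists in the KB by construction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Union

import edlib

from .embedding import CandidateMatch, EmbeddingBackend, ExactVectorIndex
from .llm import (
    LlmClient,
    assignment_prompt,
    extraction_prompt,
    validate_choice,
    validate_phrase_list,
)
from .ontology import SOURCE_PRIORITY, KnowledgeBase, normalize_phrase


@dataclass
class AnnotatorConfig:
    """Tunable knobs of the annotation cascade."""

    k: int = 20                      # retrieval depth of the semantic path
    fuzzy_threshold: float = 0.95    # auto-accept ratio for the fuzzy shortcut
    extraction_prompt: str | None = None  # None = package default
    assignment_prompt: str | None = None


@dataclass
class ExtractedPhrase:
    text: str
    span: tuple[int, int] | None  # 0-based half-open interval, None if paraphrased
    sentence: str


@dataclass
class Assignment:
    phrase: ExtractedPhrase
    hpo_id: str
    term_label: str
    provenance: str  # exact | fuzzy | model
    candidates_offered: int = 0
    similarity_of_choice: float | None = None


@dataclass
class AssignmentFailure:
    phrase: ExtractedPhrase
    reason: str


@dataclass
class CaseResult:
    note_id: str
    assignments: list[Assignment]
    failures: list[AssignmentFailure]
    unique_terms: list[str]
    diagnostics: dict[str, int]


@dataclass
class DirectHit:
    """An exact or high-confidence fuzzy KB hit that bypasses the model."""

    hpo_id: str
    phrase: str
    kind: str  # exact | fuzzy
    score: float


MatchResult = Union[DirectHit, list]


# ---------------------------------------------------------------------------
# Sentence segmentation

_ABBREV = {
    "dr", "mr", "mrs", "ms", "prof", "vs", "e.g", "i.e", "etc", "approx",
    "fig", "no", "st",
}
_BOUNDARY = re.compile(r"[.!?;]")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences, split on ``.!?;`` with a
    small abbreviation guard (known abbreviations, single initials,
    decimal points)."""
    spans = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.start()
        if m.group() == ".":
            prev = text[start:end].rstrip()
            last = prev.split()[-1].lower().rstrip(".") if prev.split() else ""
            nxt = text[end + 1 : end + 2]
            if last in _ABBREV or len(last) == 1 or nxt.isdigit():
                continue
        segment = text[start : m.end()].strip()
        if segment:
            spans.append((start, m.end()))
        start = m.end()
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


def _sentence_at(text: str, pos: int) -> str:
    for s, e in split_sentences(text):
        if s <= pos < e:
            return text[s:e].strip()
    return text.strip()


def _best_overlap_sentence(text: str, phrase: str) -> str:
    """Context sentence for a paraphrased phrase: highest token overlap."""
    tokens = set(normalize_phrase(phrase).split())
    best, best_score = text.strip(), -1
    for s, e in split_sentences(text):
        sent = text[s:e]
        score = len(tokens & set(normalize_phrase(sent).split()))
        if score > best_score:
            best, best_score = sent.strip(), score
    return best


# ---------------------------------------------------------------------------
# Phase 1: extraction


def extract_phrases(
    note: str, client: LlmClient, config: AnnotatorConfig | None = None
) -> tuple[list[ExtractedPhrase], bool]:
    """Ask the model for phenotypic phrases and locate them in the note.

    Returns ``(phrases, parse_failed)``; a backend parse failure yields an
    empty list with the flag set, never an exception.
    """
    config = config or AnnotatorConfig()
    prompt = config.extraction_prompt or extraction_prompt()
    reply = client.chat(prompt, note, validate=validate_phrase_list, phase="extract")
    if not reply.ok:
        return [], True
    phrases = []
    low = note.lower()
    for text in reply.parsed:
        if not text.strip():
            continue
        pos = low.find(text.lower())
        if pos >= 0:
            span = (pos, pos + len(text))
            phrases.append(
                ExtractedPhrase(text=text, span=span, sentence=_sentence_at(note, pos))
            )
        else:  # model paraphrased; keep it, attach best-overlap context
            phrases.append(
                ExtractedPhrase(
                    text=text, span=None, sentence=_best_overlap_sentence(note, text)
                )
            )
    return phrases, False


# ---------------------------------------------------------------------------
# Phase 2: matching and assignment


def fuzzy_ratio(a: str, b: str) -> float:
    """Levenshtein similarity normalized by the longer string."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def match_phrase(
    phrase: ExtractedPhrase,
    kb: KnowledgeBase,
    index: ExactVectorIndex,
    embedder: EmbeddingBackend,
    k: int = 20,
    fuzzy_threshold: float = 0.95,
) -> MatchResult:
    """Hybrid cascade: exact -> fuzzy -> semantic top-k.

    An exact normalized match, or a fuzzy match at ratio >=
    ``fuzzy_threshold``, short-circuits to a :class:`DirectHit`; otherwise
    the phrase is embedded and the top-``k`` candidates are returned for
    model selection.
    """
    norm = normalize_phrase(phrase.text)
    exact = kb.exact_lookup(norm)
    if exact:
        return DirectHit(hpo_id=exact[0].hpo_id, phrase=exact[0].phrase, kind="exact", score=1.0)
    best_entry, best_ratio = None, 0.0
    for entry in kb.entries:
        ratio = fuzzy_ratio(norm, entry.phrase)
        if ratio > best_ratio or (
            best_entry is not None
            and ratio == best_ratio
            and (SOURCE_PRIORITY[entry.source], entry.hpo_id)
            < (SOURCE_PRIORITY[best_entry.source], best_entry.hpo_id)
        ):
            best_entry, best_ratio = entry, ratio
    if best_entry is not None and best_ratio >= fuzzy_threshold:
        return DirectHit(
            hpo_id=best_entry.hpo_id, phrase=best_entry.phrase, kind="fuzzy", score=best_ratio
        )
    vector = embedder.embed([norm])[0]
    return index.query_top_k(vector, k)


def _candidate_payload(phrase: ExtractedPhrase, candidates: list[CandidateMatch]) -> str:
    return json.dumps(
        {
            "phrase": phrase.text,
            "sentence": phrase.sentence,
            "candidates": [
                {
                    "rank": c.rank,
                    "hpo_id": c.hpo_id,
                    "label": c.label,
                    "lineage": c.lineage,
                    "organ_system": c.organ_system,
                    "similarity": round(c.similarity, 6),
                }
                for c in candidates
            ],
        },
        sort_keys=True,
    )


def assign_term(
    phrase: ExtractedPhrase,
    candidates: list[CandidateMatch],
    client: LlmClient,
    kb: KnowledgeBase,
    diagnostics: dict[str, int] | None = None,
    config: AnnotatorConfig | None = None,
) -> Assignment | AssignmentFailure:
    """Delegate final term selection to the model, constrained to the
    candidate list.

    An id outside the list triggers exactly one re-prompt; a second
    invalid id falls back to the rank-1 candidate (recorded in
    diagnostics).  An explicit ``"none"`` drops the phrase with a reason.
    """
    if not candidates:
        raise ValueError("assign_term requires a non-empty candidate list")
    config = config or AnnotatorConfig()
    diagnostics = diagnostics if diagnostics is not None else {}
    prompt = config.assignment_prompt or assignment_prompt()
    offered = {c.hpo_id: c for c in candidates}
    payload = _candidate_payload(phrase, candidates)
    user = payload
    choice: str | None = None
    for attempt in range(2):  # initial + one repair
        reply = client.chat(prompt, user, validate=validate_choice, phase="assign")
        choice = reply.parsed if reply.ok else None
        if choice is not None and (choice.lower() == "none" or choice in offered):
            break
        user = (
            payload
            + "\n\nYour previous choice was not in the candidate list. "
            + "Choose an id from the list above or answer \"none\"."
        )
        choice = None
    if choice is None:
        diagnostics["invalid_id_fallbacks"] = diagnostics.get("invalid_id_fallbacks", 0) + 1
        chosen = min(candidates, key=lambda c: c.rank)
    elif choice.lower() == "none":
        return AssignmentFailure(phrase=phrase, reason="model declined all candidates")
    else:
        chosen = offered[choice]
    return Assignment(
        phrase=phrase,
        hpo_id=chosen.hpo_id,
        term_label=chosen.label,
        provenance="model",
        candidates_offered=len(candidates),
        similarity_of_choice=chosen.similarity,
    )


# ---------------------------------------------------------------------------
# Composition


class Annotator:
    """End-to-end single-note annotation pipeline."""

    def __init__(
        self,
        kb: KnowledgeBase,
        index: ExactVectorIndex,
        client: LlmClient,
        embedder: EmbeddingBackend,
        config: AnnotatorConfig | None = None,
    ):
        self.kb = kb
        self.index = index
        self.client = client
        self.embedder = embedder
        self.config = config or AnnotatorConfig()

    def annotate(self, note_id: str, note: str) -> CaseResult:
        diagnostics: dict[str, int] = {
            "extracted": 0, "exact": 0, "fuzzy": 0, "model": 0,
            "failures": 0, "invalid_id_fallbacks": 0, "extraction_parse_failures": 0,
        }
        assignments: list[Assignment] = []
        failures: list[AssignmentFailure] = []
        if note.strip():
            phrases, parse_failed = extract_phrases(note, self.client, self.config)
        else:
            phrases, parse_failed = [], False
        if parse_failed:
            diagnostics["extraction_parse_failures"] = 1
        diagnostics["extracted"] = len(phrases)
        for phrase in phrases:
            match = match_phrase(
                phrase, self.kb, self.index, self.embedder,
                k=self.config.k, fuzzy_threshold=self.config.fuzzy_threshold,
            )
            if isinstance(match, DirectHit):
                diagnostics[match.kind] += 1
                term = self.kb.term_index[match.hpo_id]
                assignments.append(
                    Assignment(
                        phrase=phrase,
                        hpo_id=match.hpo_id,
                        term_label=term.label,
                        provenance=match.kind,
                        similarity_of_choice=None if match.kind == "exact" else match.score,
                    )
                )
                continue
            result = assign_term(
                phrase, match, self.client, self.kb, diagnostics, self.config
            )
            if isinstance(result, Assignment):
                diagnostics["model"] += 1
                assignments.append(result)
            else:
                diagnostics["failures"] += 1
                failures.append(result)
        unique_terms: list[str] = []
        for a in assignments:
            if a.hpo_id not in unique_terms:
                unique_terms.append(a.hpo_id)
        return CaseResult(
            note_id=note_id,
            assignments=assignments,
            failures=failures,
            unique_terms=unique_terms,
            diagnostics=diagnostics,
        )
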