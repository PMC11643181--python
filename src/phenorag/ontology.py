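"""Human Phenotype Ontology parsing and the phrase knowledge base.

The knowledge base (KB) is the retrieval substrate of the annotation
pipeline: a flat list of normalized surface phrases, each mapped to a
non-obsolete HPO term and carrying lineage metadata (the root-to-term
chain) and the organ system (the depth-1 child of the phenotypic
abnormality branch on that chain).  Phrases are drawn from term labels,
synonyms, definitions and comments, and may be supplemented with a
user-curated phrase dictionary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import obonet

HP_ID_PATTERN = re.compile(r"^HP:\d{7}$")

#: Canonical id of the "Phenotypic abnormality" branch entry point.
PHENOTYPIC_ABNORMALITY = "HP:0000118"

KB_SCHEMA = "phenorag-kb/1"

#: Phrase-source priority for duplicate collapse (lower = higher priority).
SOURCE_PRIORITY = {"label": 0, "synonym": 1, "definition": 2, "comment": 3, "custom": 4}


class OntologyError(ValueError):
    """Structural problem in an ontology file (dangling parent, no root...)."""


class KBSchemaError(ValueError):
    """A serialized knowledge base could not be read back."""


def normalize_phrase(text: str) -> str:
    """Normalize a surface phrase: lower-case, collapse whitespace, strip
    surrounding punctuation.  No stemming — exact-match semantics stay
    auditable."""
    collapsed = re.sub(r"\s+", " ", text.strip().lower())
    return collapsed.strip(" \t.,;:!?\"'()[]{}")


@dataclass
class HpoTerm:
    """One ontology node."""

    id: str
    label: str
    definition: str = ""
    comments: str = ""
    synonyms: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    obsolete: bool = False
    replaced_by: str | None = None

    def __post_init__(self) -> None:
        if not HP_ID_PATTERN.match(self.id):
            raise OntologyError(f"malformed HPO identifier: {self.id!r}")


@dataclass
class PhraseEntry:
    """One KB row: a normalized surface phrase mapped to an HPO term.

    ``lineage`` is the canonical root-to-term chain of ``(id, label)``
    pairs; ``organ_system`` is the label of the depth-1 ancestor under the
    phenotypic-abnormality branch, or ``""`` for terms outside it.
    """

    phrase: str
    hpo_id: str
    source: str
    lineage: list[tuple[str, str]]
    organ_system: str

    def lineage_str(self) -> str:
        return " > ".join(label for _, label in self.lineage)


@dataclass
class KnowledgeBase:
    entries: list[PhraseEntry]
    term_index: dict[str, HpoTerm]
    version: str

    def __post_init__(self) -> None:
        self._by_phrase: dict[str, list[PhraseEntry]] = {}
        for e in self.entries:
            self._by_phrase.setdefault(e.phrase, []).append(e)

    def exact_lookup(self, phrase: str) -> list[PhraseEntry]:
        """All entries whose normalized phrase equals ``normalize_phrase(phrase)``,
        best source first, ties broken by ascending HPO id."""
        hits = self._by_phrase.get(normalize_phrase(phrase), [])
        return sorted(hits, key=lambda e: (SOURCE_PRIORITY[e.source], e.hpo_id))

    def __contains__(self, hpo_id: str) -> bool:
        return hpo_id in self.term_index


# ---------------------------------------------------------------------------
# Parsing


def _clean_obo_quoted(value: str) -> str:
    """Strip OBO trailing xref lists and surrounding quotes from def/synonym."""
    m = re.match(r'^"(.*)"', value, flags=re.S)
    return m.group(1) if m else value


def parse_ontology(path: str | Path, dialect: str = "obo") -> dict[str, HpoTerm]:
    """Parse an HPO release into a map id -> :class:`HpoTerm`.

    Parameters
    ----------
    path
        Ontology file.
    dialect
        ``"obo"`` for OBO 1.2/1.4 flat files, ``"hpo_json"`` for the
        OBO-Graphs JSON release dialect.

    Obsolete terms are retained and flagged.  A parent reference to an id
    absent from the file raises :class:`OntologyError` naming the offender.
    """
    path = Path(path)
    if dialect == "obo":
        terms = _parse_obo(path)
    elif dialect == "hpo_json":
        terms = _parse_hpo_json(path)
    else:
        raise ValueError(f"unknown ontology dialect: {dialect!r}")
    for term in terms.values():
        for parent in term.parents:
            if parent not in terms:
                raise OntologyError(
                    f"term {term.id} references missing parent {parent}"
                )
    return terms


def _parse_obo(path: Path) -> dict[str, HpoTerm]:
    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms: dict[str, HpoTerm] = {}
    for node_id, data in graph.nodes(data=True):
        if not HP_ID_PATTERN.match(node_id):
            continue
        if not data:  # bare node created by a dangling edge target
            continue
        synonyms = [_clean_obo_quoted(s) for s in data.get("synonym", [])]
        replaced = data.get("replaced_by") or None
        terms[node_id] = HpoTerm(
            id=node_id,
            label=data.get("name", ""),
            definition=_clean_obo_quoted(data.get("def", "")),
            comments=data.get("comment", ""),
            synonyms=synonyms,
            parents=sorted(data.get("is_a", [])),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            replaced_by=replaced[0] if replaced else None,
        )
    return terms


_OBO_IRI = re.compile(r"HP_(\d{7})$")


def _iri_to_id(iri: str) -> str | None:
    m = _OBO_IRI.search(iri)
    return f"HP:{m.group(1)}" if m else None


def _parse_hpo_json(path: Path) -> dict[str, HpoTerm]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        graphs = doc["graphs"]
    except (TypeError, KeyError) as exc:
        raise OntologyError(f"{path} is not an OBO-Graphs JSON document") from exc
    terms: dict[str, HpoTerm] = {}
    parents: dict[str, set[str]] = {}
    for g in graphs:
        for node in g.get("nodes", []):
            hid = _iri_to_id(node.get("id", ""))
            if hid is None or node.get("type", "CLASS") != "CLASS":
                continue
            meta = node.get("meta", {}) or {}
            replaced = None
            for bpv in meta.get("basicPropertyValues", []):
                if bpv.get("pred", "").endswith("IAO_0100001"):
                    replaced = _iri_to_id(bpv.get("val", "")) or bpv.get("val")
            terms[hid] = HpoTerm(
                id=hid,
                label=node.get("lbl", ""),
                definition=(meta.get("definition") or {}).get("val", ""),
                comments=" ".join(meta.get("comments", [])),
                synonyms=[s["val"] for s in meta.get("synonyms", []) if "val" in s],
                parents=[],
                obsolete=bool(meta.get("deprecated", False)),
                replaced_by=replaced,
            )
        for edge in g.get("edges", []):
            if edge.get("pred") != "is_a":
                continue
            child, parent = _iri_to_id(edge.get("sub", "")), _iri_to_id(edge.get("obj", ""))
            if child and parent:
                parents.setdefault(child, set()).add(parent)
    for hid, ps in parents.items():
        if hid in terms:
            terms[hid].parents = sorted(ps)
    return terms


def find_root(terms: Mapping[str, HpoTerm]) -> str:
    """The unique non-obsolete term with no parents."""
    roots = [t.id for t in terms.values() if not t.parents and not t.obsolete]
    if len(roots) != 1:
        raise OntologyError(f"expected exactly one root, found {sorted(roots)}")
    return roots[0]


# ---------------------------------------------------------------------------
# Lineage and graph queries


def canonical_path(terms: Mapping[str, HpoTerm], hpo_id: str) -> list[tuple[str, str]]:
    """Root-to-term chain choosing the lexicographically smallest
    non-obsolete parent at every step.  Display metadata only; graph
    queries use :func:`ancestors` over all parents."""
    chain: list[tuple[str, str]] = []
    current = hpo_id
    seen: set[str] = set()
    while True:
        if current in seen:
            raise OntologyError(f"cycle in parent links at {current}")
        seen.add(current)
        term = terms[current]
        chain.append((term.id, term.label))
        live_parents = [p for p in term.parents if not terms[p].obsolete]
        if not live_parents:
            break
        current = min(live_parents)
    chain.reverse()
    return chain


def organ_system_of(terms: Mapping[str, HpoTerm], hpo_id: str) -> str:
    """Label of the depth-1 child of the phenotypic-abnormality branch on
    the canonical root path; empty for terms outside that branch."""
    path = canonical_path(terms, hpo_id)
    ids = [i for i, _ in path]
    if PHENOTYPIC_ABNORMALITY not in ids:
        return ""
    pos = ids.index(PHENOTYPIC_ABNORMALITY)
    if pos + 1 >= len(path):
        return ""
    return path[pos + 1][1]


def ancestors(kb: KnowledgeBase, hpo_id: str) -> set[str]:
    """Transitive closure over all parent links, excluding ``hpo_id``."""
    return ancestors_of(kb.term_index, hpo_id)


def ancestors_of(terms: Mapping[str, HpoTerm], hpo_id: str) -> set[str]:
    if hpo_id not in terms:
        raise KeyError(f"unknown HPO id: {hpo_id}")
    out: set[str] = set()
    stack = list(terms[hpo_id].parents)
    while stack:
        p = stack.pop()
        if p not in out:
            out.add(p)
            stack.extend(terms[p].parents)
    return out


# ---------------------------------------------------------------------------
# KB construction


def build_phrase_map(
    terms: Mapping[str, HpoTerm],
    include_sources: Iterable[str] = ("label", "synonym", "definition", "comment"),
    version: str = "",
) -> KnowledgeBase:
    """Build the phrase knowledge base from parsed terms.

    One entry per distinct (normalized phrase, term) pair drawn from the
    requested sources; obsolete terms contribute nothing; duplicates
    collapse keeping the highest-priority source
    (label > synonym > definition > comment).
    """
    if not terms:
        raise OntologyError("cannot build a knowledge base from zero terms")
    wanted = set(include_sources)
    unknown = wanted - set(SOURCE_PRIORITY)
    if unknown:
        raise ValueError(f"unknown phrase sources: {sorted(unknown)}")
    find_root(terms)  # raises if the ontology has no unique root
    best: dict[tuple[str, str], str] = {}
    for term in terms.values():
        if term.obsolete:
            continue
        surfaces: list[tuple[str, str]] = []
        if "label" in wanted:
            surfaces.append(("label", term.label))
        if "synonym" in wanted:
            surfaces.extend(("synonym", s) for s in term.synonyms)
        if "definition" in wanted and term.definition:
            surfaces.append(("definition", term.definition))
        if "comment" in wanted and term.comments:
            surfaces.append(("comment", term.comments))
        for source, raw in surfaces:
            phrase = normalize_phrase(raw)
            if not phrase:
                continue
            key = (phrase, term.id)
            if key not in best or SOURCE_PRIORITY[source] < SOURCE_PRIORITY[best[key]]:
                best[key] = source
    if not best:
        raise OntologyError("knowledge base would be empty (all terms obsolete?)")
    entries = [
        PhraseEntry(
            phrase=phrase,
            hpo_id=hpo_id,
            source=source,
            lineage=canonical_path(terms, hpo_id),
            organ_system=organ_system_of(terms, hpo_id),
        )
        for (phrase, hpo_id), source in sorted(best.items())
    ]
    return KnowledgeBase(entries=entries, term_index=dict(terms), version=version)


@dataclass
class MergeReport:
    added: list[tuple[str, str]] = field(default_factory=list)
    remapped: list[tuple[str, str, str]] = field(default_factory=list)  # phrase, old, new
    rejected: list[tuple[str, str, str]] = field(default_factory=list)  # phrase, id, reason


def merge_custom_phrases(
    kb: KnowledgeBase, custom: Mapping[str, str]
) -> tuple[KnowledgeBase, MergeReport]:
    """Merge a user phrase dictionary (flat map phrase -> HPO id) into a KB.

    New entries carry ``source="custom"``.  Entries pointing at unknown ids
    are rejected and reported; entries pointing at an obsolete term that
    names a replacement are remapped to the replacement and flagged.
    """
    report = MergeReport()
    new_entries = list(kb.entries)
    existing = {(e.phrase, e.hpo_id) for e in kb.entries}
    for raw_phrase, raw_id in sorted(custom.items()):
        phrase = normalize_phrase(raw_phrase)
        hpo_id = str(raw_id).strip()
        if not phrase:
            report.rejected.append((raw_phrase, hpo_id, "empty phrase"))
            continue
        if not HP_ID_PATTERN.match(hpo_id):
            report.rejected.append((raw_phrase, hpo_id, "malformed HPO identifier"))
            continue
        if hpo_id not in kb.term_index:
            report.rejected.append((raw_phrase, hpo_id, "unknown HPO id"))
            continue
        term = kb.term_index[hpo_id]
        if term.obsolete:
            target = term.replaced_by
            if target and target in kb.term_index and not kb.term_index[target].obsolete:
                report.remapped.append((phrase, hpo_id, target))
                hpo_id = target
            else:
                report.rejected.append((raw_phrase, hpo_id, "obsolete term"))
                continue
        if (phrase, hpo_id) in existing:
            continue
        entry = PhraseEntry(
            phrase=phrase,
            hpo_id=hpo_id,
            source="custom",
            lineage=canonical_path(kb.term_index, hpo_id),
            organ_system=organ_system_of(kb.term_index, hpo_id),
        )
        new_entries.append(entry)
        existing.add((phrase, hpo_id))
        report.added.append((phrase, hpo_id))
    merged = KnowledgeBase(
        entries=sorted(new_entries, key=lambda e: (e.phrase, e.hpo_id)),
        term_index=kb.term_index,
        version=kb.version,
    )
    return merged, report


# ---------------------------------------------------------------------------
# Serialization


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the KB as a JSON document; byte-stable given sorted keys."""
    doc = {
        "schema": KB_SCHEMA,
        "version": kb.version,
        "terms": {tid: asdict(t) for tid, t in kb.term_index.items()},
        "entries": [
            {
                "phrase": e.phrase,
                "hpo_id": e.hpo_id,
                "source": e.source,
                "lineage": [list(pair) for pair in e.lineage],
                "organ_system": e.organ_system,
            }
            for e in kb.entries
        ],
    }
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, ensure_ascii=False, indent=None), encoding="utf-8"
    )


def load_kb(path: str | Path) -> KnowledgeBase:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise KBSchemaError(f"{path}: not a valid KB file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("schema") != KB_SCHEMA:
        raise KBSchemaError(
            f"{path}: expected schema {KB_SCHEMA!r}, found {doc.get('schema') if isinstance(doc, dict) else type(doc).__name__!r}"
        )
    terms = {tid: HpoTerm(**t) for tid, t in doc["terms"].items()}
    entries = [
        PhraseEntry(
            phrase=e["phrase"],
            hpo_id=e["hpo_id"],
            source=e["source"],
            lineage=[tuple(pair) for pair in e["lineage"]],
            organ_system=e["organ_system"],
        )
        for e in doc["entries"]
    ]
    return KnowledgeBase(entries=entries, term_index=terms, version=doc["version"])
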