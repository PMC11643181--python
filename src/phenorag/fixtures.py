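"""Deterministic test-scale data: a mini-ontology, synthetic clinical
notes with planted ground truth, and the published side-by-side worked
example encoded as machine-readable data.

The mini-ontology is a ~30-term DAG with the structural features the
pipeline and the false-positive taxonomy exercise: a phenotypic-
abnormality branch with several organ systems, a multi-parent term, an
obsolete term with a replacement, a branch outside phenotypic
abnormality, and the specific ancestry fragments the worked example
relies on (HP:0000206 and HP:0034417 both under HP:0000163; HP:0000969
above HP:0010742).

Synthetic notes are assembled from templated clinical sentences around
phrases sampled from the knowledge base, so planted terms are verbatim
KB surface forms; distractor sentences carry an explicit negation or
family-attribution cue and their ids must NOT be recovered.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ontology import KnowledgeBase

# ---------------------------------------------------------------------------
# Mini ontology
#
# (id, label, parents, synonyms) — parents empty only for the root.

_TERMS: list[tuple[str, str, list[str], list[str]]] = [
    ("HP:0000001", "All", [], []),
    ("HP:0000005", "Mode of inheritance", ["HP:0000001"], []),
    ("HP:0000006", "Autosomal dominant inheritance", ["HP:0000005"], []),
    ("HP:0000118", "Phenotypic abnormality", ["HP:0000001"], []),
    # organ systems (depth 1 under HP:0000118)
    ("HP:0000152", "Abnormality of head or neck", ["HP:0000118"], []),
    ("HP:0000707", "Abnormality of the nervous system", ["HP:0000118"], []),
    ("HP:0000924", "Abnormality of the skeletal system", ["HP:0000118"], []),
    ("HP:0001574", "Abnormality of the integument", ["HP:0000118"], []),
    ("HP:0025142", "Constitutional symptom", ["HP:0000118"], []),
    ("HP:0040064", "Abnormality of limbs", ["HP:0000118"], []),
    # head & neck / oral cavity
    ("HP:0000153", "Abnormality of the mouth", ["HP:0000152"], []),
    ("HP:0000163", "Abnormal oral cavity morphology", ["HP:0000153"], []),
    ("HP:0000206", "Glossitis", ["HP:0000163"], ["Tongue inflammation"]),
    ("HP:0000221", "Furrowed tongue", ["HP:0000163"], ["Scrotal tongue"]),
    ("HP:0034417", "Intraoral laceration", ["HP:0000163"], ["Tongue laceration"]),
    # integument
    ("HP:0000964", "Eczema", ["HP:0001574"], ["Eczematous dermatitis"]),
    ("HP:0000969", "Edema", ["HP:0001574"], ["Swelling", "Dropsy"]),
    ("HP:0000970", "Anhidrosis", ["HP:0001574"], ["Inability to sweat"]),
    # multi-parent: limb edema sits under both Edema and Abnormality of limbs
    ("HP:0010742", "Swollen left arm", ["HP:0000969", "HP:0040064"], ["Edema of the arm"]),
    # skeletal
    ("HP:0020110", "Bone fracture", ["HP:0000924"], ["Broken bone"]),
    ("HP:0003987", "Old ulna fracture", ["HP:0020110"], ["Ulnar fracture"]),
    ("HP:0041081", "Healed fracture right lower leg", ["HP:0020110"], ["Fractured lower leg"]),
    ("HP:0002757", "Recurrent fracture", ["HP:0020110"], ["Multiple spontaneous fractures"]),
    ("HP:0001367", "Abnormal joint morphology", ["HP:0000924"], []),
    ("HP:0002821", "Charcot joints", ["HP:0001367"], ["Neuropathic arthropathy"]),
    # nervous system
    ("HP:0012758", "Neurodevelopmental abnormality", ["HP:0000707"], []),
    ("HP:0001263", "Delayed milestones", ["HP:0012758"], ["Global developmental delay"]),
    ("HP:0001328", "Mild learning difficulties", ["HP:0012758"], ["Specific learning disability"]),
    ("HP:0034434", "Communication difficulties", ["HP:0012758"], ["Impaired communication"]),
    # constitutional
    ("HP:0012531", "Pain", ["HP:0025142"], []),
    ("HP:0025406", "Asthenia", ["HP:0025142"], ["Weak"]),
]

#: Obsolete term with a named replacement, exercising remapping.
_OBSOLETE = ("HP:0006556", "obsolete Tongue inflammation", "HP:0000206")


def make_mini_ontology(seed: int = 0, path: str | Path | None = None) -> str:
    """Emit the mini-ontology as OBO 1.2 text (byte-identical for a fixed
    seed; the current generator is seed-independent, the parameter is kept
    for interface stability).  Optionally write it to ``path``."""
    del seed
    lines = ["format-version: 1.2", "data-version: hp/mini-fixture-1", "ontology: hp-mini", ""]
    for tid, label, parents, synonyms in _TERMS:
        lines += [f"[Term]", f"id: {tid}", f"name: {label}"]
        lines.append(f'def: "{label}, as a clinical finding." []')
        for syn in synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for p in parents:
            lines.append(f"is_a: {p}")
        lines.append("")
    oid, olabel, replacement = _OBSOLETE
    lines += [
        "[Term]",
        f"id: {oid}",
        f"name: {olabel}",
        "is_obsolete: true",
        f"replaced_by: {replacement}",
        "",
    ]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Synthetic cases


@dataclass
class SyntheticCase:
    note_id: str
    text: str
    truth: list[tuple[str, str]]        # (phrase, hpo_id) planted as patient findings
    distractors: list[tuple[str, str]]  # (phrase, hpo_id) planted negated/family


_TRUTH_TEMPLATES = [
    "The patient presented with {x}.",
    "Physical examination was notable for {x}.",
    "Review of prior records documented {x}.",
    "The clinical team also noted {x}.",
]
_DISTRACTOR_TEMPLATES = [
    "There was no evidence of {x}.",
    "Her mother had {x}.",
]


def _eligible_entries(kb: KnowledgeBase):
    """Label/synonym phrases of terms inside an organ-system branch: the
    sampling pool for planted findings."""
    pool = [
        e for e in kb.entries
        if e.source in ("label", "synonym") and e.organ_system
    ]
    return sorted(pool, key=lambda e: (e.hpo_id, e.phrase))


def _conflicts(phrase: str, chosen: list[str]) -> bool:
    return any(phrase in c or c in phrase for c in chosen)


def make_cases(
    kb: KnowledgeBase,
    n_cases: int = 10,
    phrases_per_case: int = 16,
    distractor_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SyntheticCase], dict[str, list[str]]]:
    """Generate synthetic notes with planted ground truth.

    Per case, ``phrases_per_case`` distinct terms are sampled without
    replacement; one label/synonym surface phrase is planted per term,
    skipping phrases in a substring relation with an already-planted one
    so every planted phrase occurs verbatim exactly once.  With
    probability ``distractor_rate`` per planted finding, an additional
    negated or family-history sentence is planted whose term must not be
    recovered.  Returns the cases and the companion standard map
    ``{note_id: [planted ids]}``.
    """
    rng = np.random.default_rng(seed)
    pool = _eligible_entries(kb)
    by_term: dict[str, list] = {}
    for e in pool:
        by_term.setdefault(e.hpo_id, []).append(e)
    term_ids = sorted(by_term)
    if len(term_ids) < phrases_per_case:
        raise ValueError(
            f"knowledge base offers {len(term_ids)} usable terms, "
            f"need {phrases_per_case} per case"
        )
    cases, standard = [], {}
    for case_idx in range(n_cases):
        note_id = f"case-{case_idx:03d}"
        order = rng.permutation(len(term_ids))
        truth: list[tuple[str, str]] = []
        chosen_phrases: list[str] = []
        for ti in order:
            if len(truth) == phrases_per_case:
                break
            entries = by_term[term_ids[ti]]
            pick = entries[int(rng.integers(len(entries)))]
            options = [pick] + [e for e in entries if e is not pick]
            for entry in options:
                if not _conflicts(entry.phrase, chosen_phrases):
                    truth.append((entry.phrase, entry.hpo_id))
                    chosen_phrases.append(entry.phrase)
                    break
        if len(truth) < phrases_per_case:
            raise ValueError(
                f"could not place {phrases_per_case} non-overlapping phrases "
                f"for {note_id}; KB phrase pool too entangled"
            )
        distractors: list[tuple[str, str]] = []
        remaining = [t for i, t in enumerate(term_ids) if t not in {h for _, h in truth}]
        for _ in range(len(truth)):
            if not remaining or rng.random() >= distractor_rate:
                continue
            tid = remaining.pop(int(rng.integers(len(remaining))))
            entries = [
                e for e in by_term[tid] if not _conflicts(e.phrase, chosen_phrases)
            ]
            if entries:
                entry = entries[int(rng.integers(len(entries)))]
                distractors.append((entry.phrase, entry.hpo_id))
                chosen_phrases.append(entry.phrase)
        sentences = [
            _TRUTH_TEMPLATES[i % len(_TRUTH_TEMPLATES)].format(x=phrase)
            for i, (phrase, _) in enumerate(truth)
        ]
        sentences += [
            _DISTRACTOR_TEMPLATES[i % len(_DISTRACTOR_TEMPLATES)].format(x=phrase)
            for i, (phrase, _) in enumerate(distractors)
        ]
        cases.append(
            SyntheticCase(
                note_id=note_id,
                text=" ".join(sentences),
                truth=truth,
                distractors=distractors,
            )
        )
        standard[note_id] = [hpo_id for _, hpo_id in truth]
    return cases, standard


def cases_to_csv(cases: list[SyntheticCase], path: str | Path) -> None:
    """Write cases in the batch-input CSV dialect (id, clinical_text)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\r\n")
        writer.writerow(["id", "clinical_text"])
        for case in cases:
            writer.writerow([case.note_id, case.text])


def standard_to_json(standard: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(standard, sort_keys=True, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Worked example (published side-by-side tool comparison)


@dataclass
class WorkedExample:
    passage: str
    predictions: dict[str, list[str]]
    standard: list[str]
    phrase_lexicon: dict[str, str]


def worked_example() -> WorkedExample:
    """The published sample case: per-tool HPO prediction lists and the
    reconstructed 8-term manually annotated standard.

    The passage here is a synthetic stand-in composed to contain the
    published identified phrases verbatim (the original case passage is a
    figure, not machine-readable text).  The standard is the seven
    correctly assigned retrieval-pipeline terms plus HP:0034417, the
    better fit for the tongue-laceration phrase over the predicted
    HP:0000206.
    """
    passage = (
        "An 8 year old boy was referred after his parents noted healed tongue "
        "lacerations and a swollen left arm. He carries a diagnosis of "
        "Congenital Insensitivity to Pain and Anhidrosis. Imaging revealed an "
        "old ulna fracture and a healed fracture right lower leg. His skin "
        "showed eczema. School reports describe mild learning difficulties and "
        "delayed milestones. He remains at risk of Charcot joints."
    )
    predictions = {
        "rag": [
            "HP:0000206", "HP:0010742", "HP:0003987", "HP:0041081",
            "HP:0000964", "HP:0001328", "HP:0001263", "HP:0002821",
        ],
        "doc2hpo": ["HP:0000964", "HP:0001263", "HP:0000970", "HP:0012531"],
        "clinphen": ["HP:0001263", "HP:0002821"],
        "fasthpocr": [
            "HP:0003987", "HP:0000964", "HP:0001263", "HP:0002821",
            "HP:0000970", "HP:0012531", "HP:0000969", "HP:0002757",
            "HP:0034434", "HP:0025406",
        ],
    }
    standard = [
        "HP:0010742", "HP:0003987", "HP:0041081", "HP:0000964",
        "HP:0001328", "HP:0001263", "HP:0002821", "HP:0034417",
    ]
    phrase_lexicon = {
        "healed tongue lacerations": "HP:0000206",
        "swollen left arm": "HP:0010742",
        "old ulna fracture": "HP:0003987",
        "healed fracture right lower leg": "HP:0041081",
        "eczema": "HP:0000964",
        "mild learning difficulties": "HP:0001328",
        "delayed milestones": "HP:0001263",
        "charcot joints": "HP:0002821",
    }
    return WorkedExample(
        passage=passage,
        predictions=predictions,
        standard=standard,
        phrase_lexicon=phrase_lexicon,
    )


def benchmark_counts() -> dict[str, tuple[int, int, int]]:
    """Published cohort-level (TP, FP, FN) counts per tool on the 112-case
    benchmark, as printed in the comparison table."""
    return {
        "rag": (1368, 257, 424),
        "doc2hpo": (643, 251, 1150),
        "clinphen": (642, 364, 1150),
        "fasthpocr": (820, 721, 973),
    }


def fp_taxonomy_counts() -> dict[str, int]:
    """Published false-positive taxonomy for the retrieval pipeline:
    256 cohort false positives, of which 7 hallucinations, 86 unrelated,
    and 163 ontological relatives of a target term."""
    return {"total_fp": 256, "hallucination": 7, "unrelated": 86, "related": 163}


def benchmark_cohort_shape() -> dict[str, int]:
    """Published benchmark cohort shape: 112 retained cases (of 120
    collected), 1792 standard terms, minimum 3 terms per case."""
    return {"cases": 112, "standard_terms": 1792, "min_terms_per_case": 3}
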