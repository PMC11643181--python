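"""Ontology parsing, phrase-map construction, and graph queries."""

import json

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from phenorag import ontology
from phenorag.ontology import (
    HpoTerm,
    KBSchemaError,
    OntologyError,
    ancestors,
    build_phrase_map,
    load_kb,
    merge_custom_phrases,
    normalize_phrase,
    parse_ontology,
    save_kb,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Furrowed Tongue", "furrowed tongue"),
            ("  spaced\t out \n phrase ", "spaced out phrase"),
            ('"Quoted."', "quoted"),
            ("(Edema)", "edema"),
        ],
    )
    def test_folding(self, raw, expected):
        assert normalize_phrase(raw) == expected

    @given(st.text(max_size=60))
    def test_idempotent(self, text):
        once = normalize_phrase(text)
        assert normalize_phrase(once) == once


class TestParse:
    def test_mini_ontology_roundtrip(self, terms):
        assert len(terms) == 32
        glossitis = terms["HP:0000206"]
        assert glossitis.label == "Glossitis"
        assert glossitis.parents == ["HP:0000163"]
        assert "Tongue inflammation" in glossitis.synonyms
        assert ontology.find_root(terms) == "HP:0000001"

    def test_obsolete_term_flagged_with_replacement(self, terms):
        obsolete = terms["HP:0006556"]
        assert obsolete.obsolete
        assert obsolete.replaced_by == "HP:0000206"

    def test_multi_parent_term(self, terms):
        assert terms["HP:0010742"].parents == ["HP:0000969", "HP:0040064"]

    def test_root_only_ontology(self, tmp_path):
        path = tmp_path / "root.obo"
        path.write_text(
            "format-version: 1.2\nontology: hp\n\n[Term]\nid: HP:0000001\nname: All\n"
        )
        terms = parse_ontology(path)
        assert set(terms) == {"HP:0000001"}
        assert terms["HP:0000001"].parents == []

    def test_dangling_parent_names_offender(self, tmp_path):
        path = tmp_path / "bad.obo"
        path.write_text(
            "format-version: 1.2\nontology: hp\n\n"
            "[Term]\nid: HP:0000001\nname: All\n\n"
            "[Term]\nid: HP:0000002\nname: Child\nis_a: HP:0099999\n"
        )
        with pytest.raises(OntologyError, match="HP:0000002.*HP:0099999"):
            parse_ontology(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            parse_ontology(tmp_path / "absent.obo")

    def test_hpo_json_dialect(self, tmp_path):
        base = "http://purl.obolibrary.org/obo/"
        doc = {
            "graphs": [
                {
                    "nodes": [
                        {"id": base + "HP_0000001", "lbl": "All"},
                        {
                            "id": base + "HP_0000118",
                            "lbl": "Phenotypic abnormality",
                            "meta": {
                                "definition": {"val": "An abnormality."},
                                "synonyms": [{"val": "Organ abnormality"}],
                            },
                        },
                        {
                            "id": base + "HP_0006556",
                            "lbl": "obsolete thing",
                            "meta": {
                                "deprecated": True,
                                "basicPropertyValues": [
                                    {
                                        "pred": base + "IAO_0100001",
                                        "val": base + "HP_0000118",
                                    }
                                ],
                            },
                        },
                    ],
                    "edges": [
                        {
                            "sub": base + "HP_0000118",
                            "pred": "is_a",
                            "obj": base + "HP_0000001",
                        }
                    ],
                }
            ]
        }
        path = tmp_path / "hp.json"
        path.write_text(json.dumps(doc))
        terms = parse_ontology(path, dialect="hpo_json")
        assert terms["HP:0000118"].parents == ["HP:0000001"]
        assert terms["HP:0000118"].synonyms == ["Organ abnormality"]
        assert terms["HP:0000118"].definition == "An abnormality."
        assert terms["HP:0006556"].obsolete
        assert terms["HP:0006556"].replaced_by == "HP:0000118"


def _brute_force_phrase_pairs(terms, sources):
    pairs = set()
    for term in terms.values():
        if term.obsolete:
            continue
        surfaces = []
        if "label" in sources:
            surfaces.append(term.label)
        if "synonym" in sources:
            surfaces.extend(term.synonyms)
        if "definition" in sources and term.definition:
            surfaces.append(term.definition)
        if "comment" in sources and term.comments:
            surfaces.append(term.comments)
        for s in surfaces:
            norm = normalize_phrase(s)
            if norm:
                pairs.add((norm, term.id))
    return pairs


class TestPhraseMap:
    def test_entry_count_matches_brute_force(self, terms):
        for sources in [("label", "synonym"), ("label", "synonym", "definition", "comment")]:
            kb = build_phrase_map(terms, include_sources=sources)
            expected = _brute_force_phrase_pairs(terms, set(sources))
            assert {(e.phrase, e.hpo_id) for e in kb.entries} == expected

    def test_label_entry(self, kb):
        hits = kb.exact_lookup("Furrowed  Tongue")
        assert hits[0].hpo_id == "HP:0000221"
        assert hits[0].source == "label"

    def test_obsolete_terms_contribute_nothing(self, kb):
        assert all(e.hpo_id != "HP:0006556" for e in kb.entries)

    def test_duplicate_surface_collapses_to_label(self):
        terms = {
            "HP:0000001": HpoTerm(id="HP:0000001", label="All"),
            "HP:0000002": HpoTerm(
                id="HP:0000002",
                label="Eczema",
                synonyms=["eczema", "ECZEMA  "],
                parents=["HP:0000001"],
            ),
        }
        kb = build_phrase_map(terms, include_sources=("label", "synonym"))
        entries = [e for e in kb.entries if e.hpo_id == "HP:0000002"]
        assert len(entries) == 1
        assert entries[0].source == "label"

    def test_all_obsolete_is_build_error(self):
        terms = {
            "HP:0000001": HpoTerm(id="HP:0000001", label="All", obsolete=True),
        }
        with pytest.raises(OntologyError):
            build_phrase_map(terms)

    def test_rebuild_is_idempotent(self, terms):
        a = build_phrase_map(terms, version="v")
        b = build_phrase_map(terms, version="v")
        assert a.entries == b.entries
        assert a.term_index == b.term_index

    def test_lineage_internally_consistent(self, kb):
        for entry in kb.entries:
            assert entry.lineage == ontology.canonical_path(kb.term_index, entry.hpo_id)
            assert entry.lineage[0][0] == "HP:0000001"
            assert entry.lineage[-1][0] == entry.hpo_id
            for (parent, _), (child, _) in zip(entry.lineage, entry.lineage[1:]):
                assert parent in kb.term_index[child].parents

    def test_lineage_never_contains_obsolete(self, kb):
        for entry in kb.entries:
            assert all(not kb.term_index[i].obsolete for i, _ in entry.lineage)

    def test_organ_system_assignment(self, kb):
        assert kb.exact_lookup("eczema")[0].organ_system == "Abnormality of the integument"
        assert kb.exact_lookup("glossitis")[0].organ_system == "Abnormality of head or neck"
        # inheritance modifiers sit outside the phenotypic-abnormality branch
        assert kb.exact_lookup("autosomal dominant inheritance")[0].organ_system == ""


class TestMergeCustom:
    def test_adds_custom_entry(self, kb):
        merged, report = merge_custom_phrases(kb, {"left arm swelling": "HP:0010742"})
        assert len(merged.entries) == len(kb.entries) + 1
        assert report.added == [("left arm swelling", "HP:0010742")]
        hit = merged.exact_lookup("left arm swelling")[0]
        assert hit.source == "custom"

    def test_empty_map_is_identity(self, kb):
        merged, report = merge_custom_phrases(kb, {})
        assert merged.entries == kb.entries
        assert not report.added and not report.rejected

    def test_unknown_id_rejected_not_dropped_silently(self, kb):
        merged, report = merge_custom_phrases(kb, {"mystery": "HP:1234567"})
        assert len(merged.entries) == len(kb.entries)
        assert report.rejected == [("mystery", "HP:1234567", "unknown HPO id")]

    def test_malformed_id_rejected_per_entry(self, kb):
        merged, report = merge_custom_phrases(
            kb, {"bad": "HP:12", "good": "HP:0000964"}
        )
        assert ("bad", "HP:12", "malformed HPO identifier") in report.rejected
        assert ("good", "HP:0000964") in report.added

    def test_obsolete_target_remapped_to_replacement(self, kb):
        merged, report = merge_custom_phrases(kb, {"tongue swelling": "HP:0006556"})
        assert report.remapped == [("tongue swelling", "HP:0006556", "HP:0000206")]
        assert merged.exact_lookup("tongue swelling")[0].hpo_id == "HP:0000206"


class TestAncestors:
    def test_root_has_no_ancestors(self, kb):
        assert ancestors(kb, "HP:0000001") == set()

    def test_matches_networkx_reachability(self, kb):
        graph = nx.DiGraph()
        for term in kb.term_index.values():
            graph.add_node(term.id)
            for parent in term.parents:
                graph.add_edge(term.id, parent)  # child -> parent
        for term_id in kb.term_index:
            assert ancestors(kb, term_id) == nx.descendants(graph, term_id)

    def test_multi_parent_union(self, kb):
        up = ancestors(kb, "HP:0010742")
        assert {"HP:0000969", "HP:0040064", "HP:0001574", "HP:0000118", "HP:0000001"} <= up

    def test_published_fragment_ancestry(self, kb):
        assert "HP:0000163" in ancestors(kb, "HP:0034417")
        assert "HP:0000163" in ancestors(kb, "HP:0000206")

    def test_unknown_id_is_lookup_error(self, kb):
        with pytest.raises(KeyError):
            ancestors(kb, "HP:7777777")


class TestSerialization:
    def test_roundtrip_identity(self, kb, tmp_path):
        path = tmp_path / "kb.json"
        save_kb(kb, path)
        loaded = load_kb(path)
        assert loaded.entries == kb.entries
        assert loaded.term_index == kb.term_index
        assert loaded.version == kb.version

    def test_byte_stable(self, kb, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        save_kb(kb, a)
        save_kb(kb, b)
        assert a.read_bytes() == b.read_bytes()

    def test_truncated_file_is_schema_error(self, kb, tmp_path):
        path = tmp_path / "kb.json"
        save_kb(kb, path)
        path.write_text(path.read_text()[: 200])
        with pytest.raises(KBSchemaError):
            load_kb(path)

    def test_wrong_schema_tag(self, tmp_path):
        path = tmp_path / "kb.json"
        path.write_text(json.dumps({"schema": "other/9", "entries": []}))
        with pytest.raises(KBSchemaError, match="phenorag-kb/1"):
            load_kb(path)
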