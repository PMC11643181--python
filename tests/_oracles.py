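"""Independent brute-force oracles shared across test modules.

These deliberately re-derive results through a different route than the
implementation under test (per-row cosine scans, networkx reachability),
so agreement is evidence, not tautology.
"""

import networkx as nx
import numpy as np

from phenorag.evaluation import EvalRecord
from phenorag.ontology import PHENOTYPIC_ABNORMALITY


def brute_force_top_k(index, query, k):
    """Per-row cosine scan with the same tie-break keys as the index."""
    q = np.asarray(query, dtype=np.float64)
    q = q / np.linalg.norm(q)
    scored = []
    for i in range(len(index)):
        sim = float(np.dot(index.vectors[i], q))
        phrase, hpo_id = index.row_meta[i]
        scored.append((-sim, hpo_id, phrase))
    scored.sort()
    return [(hpo, phrase, -neg) for neg, hpo, phrase in scored[:k]]


def oracle_fp_category(fp_id, standard_ids, kb):
    """Reachability oracle on a networkx graph (edges child -> parent)."""
    graph = nx.DiGraph()
    for term in kb.term_index.values():
        graph.add_node(term.id)
        for parent in term.parents:
            graph.add_edge(term.id, parent)
    if fp_id not in graph:
        return "hallucination"

    def up(node):
        return nx.descendants(graph, node)

    targets = [t for t in standard_ids if t in graph]
    for t in targets:
        if fp_id in up(t) or t in up(fp_id):
            return "direct_ancestor"
    fp_side = {a for a in up(fp_id) | {fp_id} if PHENOTYPIC_ABNORMALITY in up(a)}
    for t in targets:
        t_side = {a for a in up(t) | {t} if PHENOTYPIC_ABNORMALITY in up(a)}
        if fp_side & t_side:
            return "indirect_relative"
    return "unrelated"


def record_from_counts(tp, fp, fn, case_id="c"):
    """An EvalRecord with the requested partition sizes (ids synthetic)."""
    return EvalRecord(
        case_id=case_id,
        tp_terms=[f"HP:{i:07d}" for i in range(1, tp + 1)],
        fp_terms=[f"HP:{i:07d}" for i in range(tp + 1, tp + fp + 1)],
        fn_terms=[f"HP:{i:07d}" for i in range(tp + fp + 1, tp + fp + fn + 1)],
    )
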