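"""Benchmark scoring: precision/recall/F1 and the false-positive taxonomy.

Predicted HPO term sets are scored against a manually annotated standard
by exact id matching.  Metrics come in two conventions — pooled
(micro-averaged: sum TP/FP/FN over cases, then take ratios) and per-case
mean (macro-averaged) — which differ whenever cases vary in size, so
both are reported with explicit labels.  Each false positive is further
classified by its ontological relationship to the standard terms:
direct relative (on one ancestry path with a target, broader or
narrower), indirect relative (shares an ancestor with a target strictly
below the phenotypic-abnormality branch entry), unrelated, or
hallucination (id absent from the ontology altogether).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from .ontology import HP_ID_PATTERN, PHENOTYPIC_ABNORMALITY, KnowledgeBase, ancestors

FP_CATEGORIES = ("direct_ancestor", "indirect_relative", "unrelated", "hallucination")


@dataclass
class MetricSet:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "MetricSet":
        if min(tp, fp, fn) < 0:
            raise ValueError("counts must be non-negative")
        precision = tp / (tp + fp) if tp + fp > 0 else None
        recall = tp / (tp + fn) if tp + fn > 0 else None
        if precision is not None and recall is not None and precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        elif precision is not None and recall is not None:
            f1 = 0.0
        else:
            f1 = None
        return cls(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


@dataclass
class EvalRecord:
    case_id: str
    tp_terms: list[str]
    fp_terms: list[str]
    fn_terms: list[str]
    fp_categories: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortSpec:
    """Case-inclusion rule: cases below ``min_terms_per_case`` standard
    terms are excluded before scoring."""

    min_terms_per_case: int = 3
    cases: list[tuple[str, list[str]]] = field(default_factory=list)

    def retained(self) -> list[tuple[str, list[str]]]:
        return [
            (cid, terms)
            for cid, terms in self.cases
            if len(set(terms)) >= self.min_terms_per_case
        ]


def _check_ids(ids: Iterable[str], what: str) -> set[str]:
    out = set(ids)
    bad = [i for i in out if not HP_ID_PATTERN.match(i)]
    if bad:
        raise ValueError(f"malformed HPO ids in {what}: {sorted(bad)}")
    return out


def score_case(
    predicted: Sequence[str], standard: Sequence[str], case_id: str = ""
) -> EvalRecord:
    """Partition predictions into TP/FP/FN by exact id matching.

    Duplicates within either list collapse before scoring; categories are
    left unfilled (see :func:`categorize_record`).
    """
    pred = _check_ids(predicted, "predictions")
    gold = _check_ids(standard, "standard")
    return EvalRecord(
        case_id=case_id,
        tp_terms=sorted(pred & gold),
        fp_terms=sorted(pred - gold),
        fn_terms=sorted(gold - pred),
    )


def compute_metrics(records: Sequence[EvalRecord], mode: str = "pooled"):
    """Aggregate metrics over cases.

    ``pooled`` sums counts then applies the formulas (micro-average);
    ``per_case_mean`` applies the formulas per case, drops cases where a
    ratio is undefined from that metric's mean, and averages
    (macro-average).
    """
    if not records:
        raise ValueError("compute_metrics requires at least one record")
    if mode == "pooled":
        return MetricSet.from_counts(
            tp=sum(len(r.tp_terms) for r in records),
            fp=sum(len(r.fp_terms) for r in records),
            fn=sum(len(r.fn_terms) for r in records),
        )
    if mode == "per_case_mean":
        per_case = [
            MetricSet.from_counts(len(r.tp_terms), len(r.fp_terms), len(r.fn_terms))
            for r in records
        ]
        out = {}
        for metric in ("precision", "recall", "f1"):
            values = [getattr(m, metric) for m in per_case if getattr(m, metric) is not None]
            out[metric] = sum(values) / len(values) if values else None
            out[f"n_{metric}"] = len(values)
        return out
    raise ValueError(f"unknown metric mode: {mode!r}")


# ---------------------------------------------------------------------------
# False-positive taxonomy


def categorize_fp(fp_id: str, standard_ids: Sequence[str], kb: KnowledgeBase) -> str:
    """Classify one false positive against the standard terms of its case."""
    category, _ = categorize_fp_detailed(fp_id, standard_ids, kb)
    return category


def categorize_fp_detailed(
    fp_id: str, standard_ids: Sequence[str], kb: KnowledgeBase
) -> tuple[str, str | None]:
    """As :func:`categorize_fp`, also reporting the sub-direction of a
    direct relative (``"ancestor_of_target"`` / ``"descendant_of_target"``)."""
    if not standard_ids:
        raise ValueError("standard_ids must be non-empty")
    if fp_id not in kb.term_index:
        return "hallucination", None
    fp_up = ancestors(kb, fp_id)
    for target in standard_ids:
        if target not in kb.term_index:
            continue
        if fp_id in ancestors(kb, target):
            return "direct_ancestor", "ancestor_of_target"
        if target in fp_up:
            return "direct_ancestor", "descendant_of_target"
    # shared ancestor strictly below the phenotypic-abnormality entry point
    fp_branch = {
        a for a in fp_up | {fp_id}
        if a in kb.term_index and PHENOTYPIC_ABNORMALITY in ancestors(kb, a)
    }
    for target in standard_ids:
        if target not in kb.term_index:
            continue
        target_branch = {
            a
            for a in ancestors(kb, target) | {target}
            if PHENOTYPIC_ABNORMALITY in ancestors(kb, a)
        }
        if fp_branch & target_branch:
            return "indirect_relative", None
    return "unrelated", None


def categorize_record(record: EvalRecord, kb: KnowledgeBase) -> EvalRecord:
    """Fill ``fp_categories`` for every FP term of a record, in place."""
    gold = record.tp_terms + record.fn_terms
    for fp_id in record.fp_terms:
        record.fp_categories[fp_id] = categorize_fp(fp_id, gold, kb)
    return record


# ---------------------------------------------------------------------------
# Tool comparison


@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    mean_diff: float
    n: int
    zero_variance: bool


def compare_tools(
    metrics_a: Sequence[float], metrics_b: Sequence[float]
) -> PairedTestResult:
    """Paired two-sided t-test on per-case metric values of two tools.

    Zero-variance differences are reported explicitly instead of NaN:
    identical vectors give p = 1, a constant nonzero shift gives p = 0.
    """
    if len(metrics_a) != len(metrics_b):
        raise ValueError("paired test requires equal-length samples")
    n = len(metrics_a)
    if n < 2:
        raise ValueError(f"paired test requires n >= 2, got n={n}")
    diffs = [a - b for a, b in zip(metrics_a, metrics_b)]
    mean_diff = sum(diffs) / n
    if all(math.isclose(d, diffs[0], abs_tol=0.0) for d in diffs):
        return PairedTestResult(
            statistic=0.0 if mean_diff == 0 else math.inf * (1 if mean_diff > 0 else -1),
            pvalue=1.0 if mean_diff == 0 else 0.0,
            mean_diff=mean_diff,
            n=n,
            zero_variance=True,
        )
    result = stats.ttest_rel(metrics_a, metrics_b, alternative="two-sided")
    return PairedTestResult(
        statistic=float(result.statistic),
        pvalue=float(result.pvalue),
        mean_diff=mean_diff,
        n=n,
        zero_variance=False,
    )
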