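"""Concordance statistics between two search-result tables.

These are the measures used to ask whether an incrementally merged result set
is interchangeable with a single full-database search: Pearson correlation of
e-values over shared (query, subject) pairs, mean per-query Kendall tau-b of
hit rankings, (log/normalized) discounted cumulative gain of ranked hits
against a relevance function, hit-count and mean-e-value ratios under a
significance threshold, containment of one hit set in the other, the
proportion of queries left without any significant hit, per-query hit
averages, and top-hit classification F1 against known class labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import f1_score as _sk_f1_score

from .m8io import AlignmentHit, ResultTable
from .merge_engine import DEFAULT_THRESHOLD, filter_threshold

__all__ = [
    "ComparisonReport",
    "UndefinedResultError",
    "pearson_concordance",
    "kendall_concordance",
    "dcg_scores",
    "containment_fraction",
    "hit_and_evalue_ratios",
    "zero_hit_proportion",
    "top_hit_f1",
    "average_hits_per_query",
    "class_relevance",
    "compare_tables",
]

logger = logging.getLogger(__name__)

#: floor for -log10 transforms of exact-zero e-values
_EVALUE_FLOOR = 1e-300


class UndefinedResultError(ValueError):
    """A statistic has no defined value on these inputs (too few shared
    pairs, zero variance, zero denominator)."""


def _quantized_evalue(e: float) -> float:
    """E-value rounded to 9 significant digits for ranking/tie purposes.

    Rescaling e-values to a common database length leaves last-ulp noise, so
    hits whose e-values are genuinely tied (equal bit scores) can differ in
    the 16th digit between a merged and a direct search.  Ranking on the
    quantized value lets the deterministic tie-breaks (bit score, subject id)
    decide instead of floating-point noise; e-values within relative 1e-9 are
    treated as equal, matching the equivalence tolerance of the merge itself.
    """
    return float(f"{e:.8e}") if e > 0 else 0.0


@dataclass(frozen=True)
class ComparisonReport:
    """All pairwise comparison statistics between tables a and b."""

    pearson: float
    kendall_tau: float
    hit_count_ratio: float
    mean_evalue_ratio: float
    containment_fraction: float
    zero_hit_proportion_a: float
    zero_hit_proportion_b: float
    mean_log_dcg_a: float
    mean_log_dcg_b: float
    mean_ndcg_a: float
    mean_ndcg_b: float
    avg_hits_per_query_a: float
    avg_hits_per_query_b: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# pairing helpers


def _best_hsp_per_pair(table: ResultTable) -> dict[tuple[str, str], AlignmentHit]:
    """Best HSP per (query, subject) pair: lowest e-value, ties by highest
    bit score."""
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in table.hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or (_quantized_evalue(h.evalue), -h.bit_score) < (
            _quantized_evalue(prev.evalue), -prev.bit_score
        ):
            best[key] = h
    return best


def _pair_set(table: ResultTable) -> set[tuple[str, str]]:
    return {(h.query_id, h.subject_id) for h in table.hits}


# ---------------------------------------------------------------------------
# correlation statistics


def pearson_concordance(
    a: ResultTable,
    b: ResultTable,
    transform: Literal["raw", "neglog10"] = "neglog10",
) -> float:
    """Pearson correlation of e-values over shared (query, subject) pairs.

    One value per pair (the best HSP); ``neglog10`` correlates
    ``-log10(e)`` (zero e-values floored at 1e-300), which is numerically
    sane when e-values span many orders of magnitude.
    """
    pa, pb = _best_hsp_per_pair(a), _best_hsp_per_pair(b)
    shared = sorted(pa.keys() & pb.keys())
    if len(shared) < 2:
        raise UndefinedResultError(
            f"need >= 2 shared (query, subject) pairs, have {len(shared)}"
        )
    xs = np.array([pa[k].evalue for k in shared])
    ys = np.array([pb[k].evalue for k in shared])
    if transform == "neglog10":
        xs = -np.log10(np.maximum(xs, _EVALUE_FLOOR))
        ys = -np.log10(np.maximum(ys, _EVALUE_FLOOR))
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedResultError("zero variance in paired e-values")
    return float(_scipy_stats.pearsonr(xs, ys).statistic)


def _rank_order(hits: Sequence[AlignmentHit]) -> list[str]:
    ordered = sorted(
        hits, key=lambda h: (_quantized_evalue(h.evalue), -h.bit_score, h.subject_id)
    )
    return [h.subject_id for h in ordered]


def kendall_concordance(a: ResultTable, b: ResultTable, pooled: bool = False) -> float:
    """Mean per-query Kendall tau-b of hit rankings over shared hits.

    Within each query, shared subjects are ranked by (e-value asc, bit score
    desc, subject id asc) in each table; queries contributing >= 2 shared
    hits each yield a tau-b, averaged uniformly.  ``pooled=True`` instead
    computes a single tau-b over all shared pairs pooled across queries
    (rankings are usually only meaningful within a query, so the per-query
    mean is the default).
    """
    pa, pb = _best_hsp_per_pair(a), _best_hsp_per_pair(b)
    shared = pa.keys() & pb.keys()
    by_query: dict[str, list[str]] = {}
    for q, s in shared:
        by_query.setdefault(q, []).append(s)

    if pooled:
        keys = sorted(shared)
        if len(keys) < 2:
            raise UndefinedResultError("need >= 2 shared pairs for pooled tau")
        xs = [pa[k].evalue for k in keys]
        ys = [pb[k].evalue for k in keys]
        return float(_scipy_stats.kendalltau(xs, ys).statistic)

    taus = []
    for q, subjects in by_query.items():
        if len(subjects) < 2:
            continue
        subj = set(subjects)
        order_a = [s for s in _rank_order([pa[(q, s)] for s in subj])]
        rank_a = {s: i for i, s in enumerate(order_a)}
        order_b = [s for s in _rank_order([pb[(q, s)] for s in subj])]
        rank_b = {s: i for i, s in enumerate(order_b)}
        xs = [rank_a[s] for s in order_a]
        ys = [rank_b[s] for s in order_a]
        taus.append(float(_scipy_stats.kendalltau(xs, ys).statistic))
    if not taus:
        raise UndefinedResultError("no query contributes >= 2 shared hits")
    return float(np.mean(taus))


# ---------------------------------------------------------------------------
# ranking quality


def class_relevance(query_labels: Mapping[str, str], subject_labels: Mapping[str, str]):
    """Default relevance: 1 when the subject's class label equals the
    query's, else 0."""

    def rel(query_id: str, subject_id: str) -> float:
        return 1.0 if query_labels.get(query_id) == subject_labels.get(subject_id) else 0.0

    return rel


def dcg_scores(
    table: ResultTable,
    relevance,
    depth: int = 20,
) -> dict[str, tuple[float, float, float]]:
    """Per-query (DCG, log DCG, nDCG) over the top ``depth`` hits.

    ``relevance`` maps (query_id, subject_id) to a non-negative gain; it may
    be a mapping or a callable.  DCG at ranks i = 1.. is
    ``sum(rel_i / log2(i + 1))``; log DCG is ``ln(1 + DCG)``; nDCG divides by
    the ideal DCG (the same gains sorted descending), with 0 when the ideal
    is 0.  The table must already be in report order.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rel_fn = relevance if callable(relevance) else lambda q, s: relevance.get((q, s), 0.0)
    per_query: dict[str, list[float]] = {}
    for h in table.hits:
        gains = per_query.setdefault(h.query_id, [])
        if len(gains) < depth:
            r = float(rel_fn(h.query_id, h.subject_id))
            if r < 0:
                raise ValueError(
                    f"negative relevance for ({h.query_id}, {h.subject_id})"
                )
            gains.append(r)
    out: dict[str, tuple[float, float, float]] = {}
    for q, gains in per_query.items():
        discounts = 1.0 / np.log2(np.arange(2, len(gains) + 2))
        dcg = float(np.dot(gains, discounts))
        ideal = float(np.dot(sorted(gains, reverse=True), discounts))
        ndcg = dcg / ideal if ideal > 0 else 0.0
        out[q] = (dcg, math.log1p(dcg), ndcg)
    return out


# ---------------------------------------------------------------------------
# set / count statistics


def containment_fraction(a: ResultTable, b: ResultTable) -> float:
    """Fraction of a's distinct (query, subject) pairs also present in b.

    Vacuously 1.0 when a has no pairs (logged)."""
    pa, pb = _pair_set(a), _pair_set(b)
    if not pa:
        logger.info("containment_fraction: table a has no pairs; vacuously 1.0")
        return 1.0
    return len(pa & pb) / len(pa)


def hit_and_evalue_ratios(
    incremental: ResultTable,
    full: ResultTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, float]:
    """(hit-count ratio, mean-e-value ratio) of incremental vs full results,
    both tables filtered at the significance threshold first.  Means are
    arithmetic."""
    inc = filter_threshold(incremental, threshold)
    ful = filter_threshold(full, threshold)
    if len(ful) == 0:
        raise UndefinedResultError("full table has no hits below threshold")
    mean_full = float(np.mean([h.evalue for h in ful.hits]))
    if mean_full == 0.0:
        raise UndefinedResultError("full table mean e-value is zero")
    count_ratio = len(inc) / len(ful)
    mean_inc = float(np.mean([h.evalue for h in inc.hits])) if len(inc) else 0.0
    return count_ratio, mean_inc / mean_full


def zero_hit_proportion(
    table: ResultTable,
    all_query_ids: set[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Fraction of queries with no hit below the threshold."""
    if not all_query_ids:
        raise ValueError("all_query_ids must be non-empty")
    if not all_query_ids >= table.query_ids():
        raise ValueError("all_query_ids must cover every query in the table")
    with_hits = {h.query_id for h in table.hits if h.evalue < threshold}
    return 1.0 - len(with_hits) / len(all_query_ids)


def average_hits_per_query(
    table: ResultTable,
    all_query_ids: set[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Hits below threshold divided by the number of queries searched —
    hitless queries count in the denominator."""
    if not all_query_ids:
        raise ValueError("all_query_ids must be non-empty")
    if not all_query_ids >= table.query_ids():
        raise ValueError("all_query_ids must cover every query in the table")
    passing = sum(1 for h in table.hits if h.evalue < threshold)
    return passing / len(all_query_ids)


# ---------------------------------------------------------------------------
# classification


def top_hit_f1(
    table: ResultTable,
    query_labels: Mapping[str, str],
    subject_labels: Mapping[str, str],
) -> float:
    """Macro-averaged F1 of class labels predicted by the e-value top hit.

    Each query's prediction is the class of its lowest-e-value hit (ties per
    the deterministic sort); queries with no hits predict nothing and count
    as wrong.  Averaging is macro over the classes present among the queries.
    """
    for h in table.hits:
        if h.query_id not in query_labels:
            raise KeyError(f"no class label for query id {h.query_id!r}")
        if h.subject_id not in subject_labels:
            raise KeyError(f"no class label for subject id {h.subject_id!r}")
    top: dict[str, AlignmentHit] = {}
    for h in table.hits:
        prev = top.get(h.query_id)
        if prev is None or (
            (h.evalue, -h.bit_score, h.subject_id, h.s_start, h.q_start)
            < (prev.evalue, -prev.bit_score, prev.subject_id, prev.s_start, prev.q_start)
        ):
            top[h.query_id] = h
    y_true, y_pred = [], []
    for q, true_label in query_labels.items():
        y_true.append(true_label)
        hit = top.get(q)
        y_pred.append(subject_labels[hit.subject_id] if hit is not None else "__no_hit__")
    classes = sorted(set(query_labels.values()))
    return float(
        _sk_f1_score(y_true, y_pred, labels=classes, average="macro", zero_division=0)
    )


# ---------------------------------------------------------------------------
# full report


def compare_tables(
    a: ResultTable,
    b: ResultTable,
    query_ids: Optional[set[str]] = None,
    query_labels: Optional[Mapping[str, str]] = None,
    subject_labels: Optional[Mapping[str, str]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    depth: int = 20,
) -> ComparisonReport:
    """Compute the full comparison report between tables a (e.g. incremental)
    and b (e.g. full search).

    DCG statistics use the class-label relevance when labels are given, else
    every hit counts as relevant (gains of 1), which reduces nDCG to 1 and
    makes log DCG a pure depth measure.
    """
    qids = query_ids or (a.query_ids() | b.query_ids())
    if query_labels and subject_labels:
        rel = class_relevance(query_labels, subject_labels)
    else:
        rel = lambda q, s: 1.0
    dcg_a = dcg_scores(a, rel, depth=depth)
    dcg_b = dcg_scores(b, rel, depth=depth)

    def _mean(scores, idx):
        return float(np.mean([v[idx] for v in scores.values()])) if scores else 0.0

    count_ratio, evalue_ratio = hit_and_evalue_ratios(a, b, threshold)
    return ComparisonReport(
        pearson=pearson_concordance(a, b),
        kendall_tau=kendall_concordance(a, b),
        hit_count_ratio=count_ratio,
        mean_evalue_ratio=evalue_ratio,
        containment_fraction=containment_fraction(b, a),
        zero_hit_proportion_a=zero_hit_proportion(a, qids, threshold),
        zero_hit_proportion_b=zero_hit_proportion(b, qids, threshold),
        mean_log_dcg_a=_mean(dcg_a, 1),
        mean_log_dcg_b=_mean(dcg_b, 1),
        mean_ndcg_a=_mean(dcg_a, 2),
        mean_ndcg_b=_mean(dcg_b, 2),
        avg_hits_per_query_a=average_hits_per_query(a, qids, threshold),
        avg_hits_per_query_b=average_hits_per_query(b, qids, threshold),
    )
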