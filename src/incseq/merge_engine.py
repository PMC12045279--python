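"""Merging batch search results into one statistically consistent table.

Each input table was searched against a disjoint database batch and carries
that batch's residue count (m8e semantics).  The merge rescales every hit's
e-value from its source-batch length to the combined length, deduplicates,
and re-ranks strictly by rescaled e-value.  Because bit scores, identities
and coordinates do not depend on database size, they pass through unchanged —
the merged table is field-for-field what a single search of the union would
have produced, for any engine whose e-values are linear in database length.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional, Sequence

from .evalue_model import combine_db_lengths, rescale_evalue
from .m8io import AlignmentHit, ResultTable

__all__ = [
    "merge_tables",
    "dedupe_hits",
    "sort_hits",
    "filter_threshold",
    "cap_hits_per_query",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: the commonly used homology e-value cutoff
DEFAULT_THRESHOLD = 1e-5


def sort_hits(hits: Sequence[AlignmentHit]) -> tuple[AlignmentHit, ...]:
    """Deterministic output order: query id, then e-value ascending, then bit
    score descending, then subject id, then subject/query start."""
    return tuple(
        sorted(
            hits,
            key=lambda h: (
                h.query_id,
                h.evalue,
                -h.bit_score,
                h.subject_id,
                h.s_start,
                h.q_start,
            ),
        )
    )


def dedupe_hits(hits: Sequence[AlignmentHit]) -> tuple[AlignmentHit, ...]:
    """Collapse duplicate HSPs.

    Hits identical in (query, subject, query coords, subject coords) are the
    same alignment reported twice (overlapping databases, re-runs); the one
    with the lowest e-value survives, ties broken by highest bit score.  Hits
    on the same (query, subject) pair with different coordinates are distinct
    HSPs and all survive.  Input hits must already share a common db_length.
    """
    best: dict[tuple, AlignmentHit] = {}
    order: list[tuple] = []
    for h in hits:
        key = (h.query_id, h.subject_id, h.q_start, h.q_end, h.s_start, h.s_end)
        prev = best.get(key)
        if prev is None:
            best[key] = h
            order.append(key)
        elif (h.evalue, -h.bit_score) < (prev.evalue, -prev.bit_score):
            best[key] = h
    return tuple(best[k] for k in order)


def merge_tables(tables: Sequence[ResultTable]) -> ResultTable:
    """Merge any number of per-batch result tables into one.

    Every table must carry its database length.  The output's db_length is
    the sum; every hit appears (after dedup) with its e-value rescaled from
    its source length to the combined length; everything else is unchanged.
    """
    if len(tables) == 0:
        raise ValueError("need at least one table to merge")
    for t in tables:
        if t.db_length is None:
            raise ValueError(
                f"table {t.source_label or '<unlabeled>'} has no db_length; "
                "merge requires m8e semantics"
            )
    total = combine_db_lengths([t.db_length for t in tables])
    logger.debug(
        "merging %d tables (%s) to combined db_length %d",
        len(tables), ", ".join(t.source_label or "?" for t in tables), total,
    )
    rescaled = []
    for t in tables:
        for h in t.hits:
            rescaled.append(replace(h, evalue=rescale_evalue(h.evalue, t.db_length, total)))
    hits = sort_hits(dedupe_hits(rescaled))
    label = "+".join(t.source_label for t in tables if t.source_label)
    return ResultTable(hits=hits, db_length=total, source_label=label)


def filter_threshold(table: ResultTable, threshold: float = DEFAULT_THRESHOLD) -> ResultTable:
    """Keep hits with e-value strictly below the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return replace(table, hits=tuple(h for h in table.hits if h.evalue < threshold))


def cap_hits_per_query(table: ResultTable, cap: Optional[int] = None) -> ResultTable:
    """Retain at most ``cap`` hits per query (the first ``cap`` in sorted
    order, i.e. the lowest e-values).  ``cap=None`` is the identity; search
    tools impose such caps by default, which suppresses hits."""
    if cap is None:
        return table
    if cap <= 0:
        raise ValueError("cap must be a positive integer")
    counts: dict[str, int] = {}
    kept = []
    for h in table.hits:
        c = counts.get(h.query_id, 0)
        if c < cap:
            kept.append(h)
            counts[h.query_id] = c + 1
    return replace(table, hits=tuple(kept))
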