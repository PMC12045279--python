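"""E-value statistics for incremental database search.

In the Karlin-Altschul extreme-value model the expected number of chance hits
scoring at least S is ``E = K * m * n * exp(-lambda * S)``, with m the query
length and n the database length in residues.  Expressed through the
normalized bit score ``S' = (lambda*S - ln K) / ln 2`` this becomes
``E = m * n * 2**(-S')``: at a fixed query and alignment score, E is exactly
linear in the database length.  That linearity is what makes incremental
search possible — a hit's e-value computed against one batch can be
recalibrated to the combined database by a single multiplicative factor,
which is all an m8/m8e row (carrying only e-value and bit score) supports.
Finite-size corrections that would need per-alignment lambda/K/area terms are
not representable in the format and are approximated by this linear scaling.

E-values driven below 1e-300 by rescaling are clamped to exact zero to avoid
denormal noise; each clamp increments a counter reported through the module
logger.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ScoringStatistics",
    "rescale_evalue",
    "combine_db_lengths",
    "karlin_altschul_evalue",
    "bit_score_from_raw",
]

logger = logging.getLogger(__name__)

#: e-values smaller than this after rescaling are clamped to exact zero
EVALUE_UNDERFLOW = 1e-300

_clamp_count = 0


def underflow_clamp_count() -> int:
    """Number of e-values clamped to zero since process start (diagnostics)."""
    return _clamp_count


@dataclass(frozen=True)
class ScoringStatistics:
    """Karlin-Altschul parameters and search-space dimensions.

    ``lam`` (lambda) is in nats per raw-score unit; ``K`` is the dimensionless
    prefactor; ``m`` and ``n`` are query and database lengths in residues.
    """

    lam: float
    K: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.m < 1 or self.n < 1:
            raise ValueError("query and database lengths must be >= 1")


def rescale_evalue(evalue: float, length_from: int, length_to: int) -> float:
    """Recalibrate an e-value from one database length to another.

    Returns ``evalue * length_to / length_from``; exact zero maps to exact
    zero.  This is the statistical core of the merge: E is proportional to
    the searched database length at fixed query and score.
    """
    if evalue < 0:
        raise ValueError("evalue must be non-negative")
    if length_from < 1 or length_to < 1:
        raise ValueError("database lengths must be >= 1")
    if evalue == 0.0:
        return 0.0
    out = evalue * (length_to / length_from)
    if out < EVALUE_UNDERFLOW:
        global _clamp_count
        _clamp_count += 1
        logger.debug(
            "e-value %g rescaled below %g; clamped to 0 (clamp #%d)",
            evalue, EVALUE_UNDERFLOW, _clamp_count,
        )
        return 0.0
    return out


def combine_db_lengths(lengths: Sequence[int]) -> int:
    """Total residue count of a union of disjoint databases."""
    if len(lengths) == 0:
        raise ValueError("need at least one database length")
    for length in lengths:
        if length < 1:
            raise ValueError("database lengths must be >= 1")
    return int(sum(lengths))


def karlin_altschul_evalue(bit_score: float, m: int, n: int) -> float:
    """E-value from a bit score: ``m * n * 2**(-bit_score)``.

    Exactly linear in n, the property the incremental merge relies on.
    """
    if m < 1 or n < 1:
        raise ValueError("query and database lengths must be >= 1")
    try:
        return m * n * math.pow(2.0, -bit_score)
    except OverflowError:
        return math.inf


def bit_score_from_raw(raw_score: float, stats: ScoringStatistics) -> float:
    """Normalized bit score ``S' = (lambda*S - ln K) / ln 2``."""
    return (stats.lam * raw_score - math.log(stats.K)) / math.log(2.0)
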