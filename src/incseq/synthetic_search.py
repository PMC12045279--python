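"""Self-contained verification substrate: synthetic protein families, a
stratified batch partitioner, and a deterministic toy search engine.

The generator emulates a structured protein database — a set of sequence
families nested in top-level classes, like a structural-domain database — so
that a held-out query batch has true homologs scattered across the remaining
batches.  The toy engine runs exhaustive affine-gap Smith-Waterman over every
query x subject pair and assigns e-values through the Karlin-Altschul model
``E = m * n * 2**(-S')``, so its e-values are *exactly* linear in database
length.  That makes it an oracle for the incremental merge: a full-database
search and merged per-batch searches must agree identically, and any
discrepancy is a merge defect, not engine noise.

Biological realism (indels in the generator, substitution matrices, domain
architecture) is deliberately out of scope; every property the engine is used
to verify is relative, so the fixed scoring constants do not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Literal, Sequence, Union

import io

import numpy as np
from numba import njit
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evalue_model import ScoringStatistics, bit_score_from_raw, karlin_altschul_evalue
from .m8io import AlignmentHit, ResultTable, compute_db_length
from .merge_engine import sort_hits

__all__ = [
    "AMINO_ACIDS",
    "SyntheticFamilySet",
    "ToyScoringParams",
    "generate_protein_families",
    "partition_batches",
    "smith_waterman_score",
    "toy_search",
    "records_to_fasta",
]

#: the 20 canonical residues; the generator never emits ambiguity codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# fixed toy statistics: typical ungapped BLOSUM-scale constants; their exact
# values are irrelevant to every property test because all checks are relative
TOY_LAMBDA = 0.267
TOY_K = 0.041


@dataclass(frozen=True)
class SyntheticFamilySet:
    """Seeded generator output: labeled protein families.

    Identifiers follow ``c<class>_f<family>_m<member>`` (all 1-based) and
    parse back to their labels; identical (config, seed) reproduce
    byte-identical records.
    """

    records: tuple[tuple[str, str], ...]
    n_classes: int
    n_families_per_class: int
    members_per_family: int
    seed: int

    def class_of(self, identifier: str) -> str:
        return identifier.split("_")[0]

    def query_label_map(self) -> dict[str, str]:
        return {ident: self.class_of(ident) for ident, _ in self.records}


@dataclass(frozen=True)
class ToyScoringParams:
    """Scoring for the toy engine: identity match/mismatch with affine gaps.

    Opening a gap costs ``gap_open + gap_extend``; each further gapped column
    costs ``gap_extend`` (all penalties are non-positive reals).
    ``min_bit_score`` is the reporting floor — filtering on bit score (which
    is independent of database size) keeps per-batch and full-database hit
    sets identical, and its default keeps desk-scale tables to hundreds of
    rows.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    lam: float = TOY_LAMBDA
    K: float = TOY_K
    min_bit_score: float = 25.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def stats(self, m: int, n: int) -> ScoringStatistics:
        return ScoringStatistics(lam=self.lam, K=self.K, m=m, n=n)


# ---------------------------------------------------------------------------
# family generation


def generate_protein_families(
    n_classes: int,
    n_families_per_class: int,
    members_per_family: int,
    parent_length: int = 120,
    mutation_rate: float = 0.1,
    seed: int = 17,
) -> SyntheticFamilySet:
    """Generate labeled protein families by point mutation from seeded parents.

    For each family one random parent sequence is drawn; each member is a copy
    with every position independently substituted (to a *different* residue)
    with probability ``mutation_rate``, so the rate is the realized per-site
    divergence from the parent.  Members of a family are therefore homologs
    at ~2x the rate from each other, while different families are unrelated
    random sequences.
    """
    if n_classes < 1 or n_families_per_class < 1 or members_per_family < 1:
        raise ValueError("counts must be positive")
    if parent_length < 20:
        raise ValueError("parent_length must be >= 20")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    n_aa = len(alphabet)
    records = []
    for c in range(1, n_classes + 1):
        for f in range(1, n_families_per_class + 1):
            parent = rng.integers(0, n_aa, size=parent_length)
            for m in range(1, members_per_family + 1):
                member = parent.copy()
                mutate = rng.random(parent_length) < mutation_rate
                # substitute with an offset in 1..19 so the residue changes
                offsets = rng.integers(1, n_aa, size=parent_length)
                member[mutate] = (member[mutate] + offsets[mutate]) % n_aa
                seq = alphabet[member].tobytes().decode()
                records.append((f"c{c}_f{f}_m{m}", seq))
    return SyntheticFamilySet(
        records=tuple(records),
        n_classes=n_classes,
        n_families_per_class=n_families_per_class,
        members_per_family=members_per_family,
        seed=seed,
    )


def partition_batches(
    records: Sequence[tuple[str, str]],
    k: int,
    strategy: Literal["stratified", "random"] = "stratified",
    seed: int = 17,
) -> list[list[tuple[str, str]]]:
    """Partition records into k disjoint batches.

    ``stratified``: within each class (parsed from the ``c<class>_`` prefix),
    a seeded shuffle followed by round-robin assignment, so every batch's
    class proportions match the whole within one record per class — the way
    a class-stratified database split preserves composition in every growth
    step.  ``random``: one seeded shuffle, contiguous equal-size split.
    """
    if k < 1 or k > len(records):
        raise ValueError("k must be in [1, number of records]")
    rng = np.random.default_rng(seed)
    batches: list[list[tuple[str, str]]] = [[] for _ in range(k)]
    if strategy == "stratified":
        by_class: dict[str, list[tuple[str, str]]] = {}
        for rec in records:
            by_class.setdefault(rec[0].split("_")[0], []).append(rec)
        for cls in sorted(by_class):
            group = by_class[cls]
            perm = rng.permutation(len(group))
            for i, j in enumerate(perm):
                batches[i % k].append(group[j])
    elif strategy == "random":
        perm = rng.permutation(len(records))
        bounds = np.array_split(perm, k)
        for b, idxs in enumerate(bounds):
            batches[b] = [records[i] for i in idxs]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return batches


def records_to_fasta(records: Sequence[tuple[str, str]]) -> str:
    """Render (identifier, sequence) pairs as FASTA text (60-column wrap)."""
    out = io.StringIO()
    SeqIO.write(
        (SeqRecord(Seq(seq), id=ident, description="") for ident, seq in records),
        out,
        "fasta",
    )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Smith-Waterman (affine gaps, deterministic traceback)

# traceback codes for H: 0 stop, 1 diagonal, 2 up (gap in b), 3 left (gap in a)


@njit(cache=True)
def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros((la + 1, lb + 1))
    E = np.full((la + 1, lb + 1), -1e30)  # gap in a (left moves)
    F = np.full((la + 1, lb + 1), -1e30)  # gap in b (up moves)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)
    eptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 1 = extend
    fptr = np.zeros((la + 1, lb + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    open_cost = gap_open + gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e_open = H[i, j - 1] + open_cost
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                eptr[i, j] = 1
            else:
                E[i, j] = e_open
                eptr[i, j] = 0
            f_open = H[i - 1, j] + open_cost
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                fptr[i, j] = 1
            else:
                F[i, j] = f_open
                fptr[i, j] = 0
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            # deterministic preference on ties: diagonal, then up, then left
            h = 0.0
            p = 0
            if diag >= h and diag >= F[i, j] and diag >= E[i, j]:
                h = diag
                p = 1
            elif F[i, j] >= h and F[i, j] >= E[i, j]:
                h = F[i, j]
                p = 2
            elif E[i, j] >= h:
                h = E[i, j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            # earliest (smallest end coordinates) cell wins score ties
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    identity = 0
    aligned = 0
    mismatches = 0
    gap_opens = 0
    i, j = bi, bj
    a_end, b_end = bi, bj
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            aligned += 1
            if a[i - 1] == b[j - 1]:
                identity += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:  # up: consume a, gap in b
            gap_opens += 1
            while fptr[i, j] == 1:
                aligned += 1
                i -= 1
            aligned += 1
            i -= 1
        else:  # left: consume b, gap in a
            gap_opens += 1
            while eptr[i, j] == 1:
                aligned += 1
                j -= 1
            aligned += 1
            j -= 1
    a_start, b_start = i + 1, j + 1
    if best == 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0, 0, 0
    return best, a_start, a_end, b_start, b_end, identity, aligned, mismatches, gap_opens


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def smith_waterman_score(
    a: str, b: str, params: ToyScoringParams = ToyScoringParams()
) -> tuple[float, int, int, int, int, int, int, int, int]:
    """Optimal affine-gap local alignment of two protein sequences.

    Returns ``(raw_score, a_start, a_end, b_start, b_end, identity_count,
    aligned_length, mismatches, gap_opens)`` with 1-based inclusive
    coordinates.  Tie-breaking is deterministic: the traceback prefers
    diagonal over up over left, and among equally scoring end cells the one
    with the smallest coordinates wins.  An all-negative comparison yields
    the empty local alignment (score 0, zeroed coordinates).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = _sw_kernel(
        _encode(a), _encode(b),
        params.match, params.mismatch, params.gap_open, params.gap_extend,
    )
    return (float(res[0]),) + tuple(int(x) for x in res[1:])


# ---------------------------------------------------------------------------
# toy search engine


def _read_fasta(src: Union[IO[str], str]) -> list[tuple[str, str]]:
    if isinstance(src, str) and "\n" not in src and not src.lstrip().startswith(">"):
        with open(src) as fh:
            return [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    if isinstance(src, str):
        src = io.StringIO(src)
    return [(r.id, str(r.seq)) for r in SeqIO.parse(src, "fasta")]


def toy_search(
    query_fasta: Union[IO[str], str],
    db_fasta: Union[IO[str], str],
    params: ToyScoringParams = ToyScoringParams(),
) -> ResultTable:
    """Exhaustive deterministic search: every query against every subject.

    Each pair is aligned by :func:`smith_waterman_score`; the raw score is
    converted to a bit score and then to an e-value with m = query length and
    n = total database residues.  Rows are reported when the bit score
    reaches ``params.min_bit_score`` — a database-size-independent criterion,
    so partitioning the database never changes which hits exist, only their
    e-values.  Output carries the database length (m8e semantics) and is
    sorted deterministically.
    """
    queries = _read_fasta(query_fasta)
    subjects = _read_fasta(db_fasta)
    if not subjects:
        raise ValueError("empty database")
    if not queries:
        raise ValueError("empty query set")
    n = sum(len(s) for _, s in subjects)
    hits = []
    for qid, qseq in queries:
        m = len(qseq)
        stats = params.stats(m, n)
        for sid, sseq in subjects:
            raw, qs, qe, ss, se, ident, alen, mism, gaps = smith_waterman_score(
                qseq, sseq, params
            )
            if raw <= 0.0 or alen == 0:
                continue
            bit = bit_score_from_raw(raw, stats)
            if bit < params.min_bit_score:
                continue
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=100.0 * ident / alen,
                    alignment_length=alen,
                    mismatches=mism,
                    gap_opens=gaps,
                    q_start=qs,
                    q_end=qe,
                    s_start=ss,
                    s_end=se,
                    evalue=karlin_altschul_evalue(bit, m, n),
                    bit_score=bit,
                )
            )
    return ResultTable(hits=sort_hits(hits), db_length=n, source_label="toy")
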