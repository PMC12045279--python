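"""Reading and writing of BLAST-tabular search results (m8) and the m8e extension.

The m8 format is the 12-column tab-separated BLAST tabular output
(``-outfmt 6``): query id, subject id, percent identity, alignment length,
mismatches, gap opens, query start/end, subject start/end, e-value, bit score.
The m8e dialect prepends a single header line carrying the total residue count
of the searched database, which makes e-value recalibration possible when
results from searches against different databases are merged.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Literal, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentHit",
    "ResultTable",
    "M8FormatError",
    "parse_result_table",
    "write_result_table",
    "attach_db_length",
    "compute_db_length",
    "read_result_table",
    "save_result_table",
]

Dialect = Literal["m8", "m8e", "auto"]

#: Tolerated alternative header form, e.g. ``#db_length:12345``.
_HEADER_RE = re.compile(r"^(?:#db_length:)?(\d+)\s*$")


class M8FormatError(ValueError):
    """Raised for malformed m8/m8e content (wrong column count, bad numbers,
    missing or invalid m8e header)."""


@dataclass(frozen=True)
class AlignmentHit:
    """One high-scoring segment pair (HSP): a single m8 row.

    Coordinates are 1-based inclusive, exactly as BLAST emits them; protein
    searches never reverse the query, so ``q_start <= q_end`` always holds.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start < 1 or self.q_end < self.q_start:
            raise ValueError(
                f"invalid query coordinates {self.q_start}-{self.q_end} "
                f"for hit {self.query_id}/{self.subject_id}"
            )
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise ValueError("mismatches and gap_opens must be non-negative")


@dataclass(frozen=True)
class ResultTable:
    """An ordered collection of hits, optionally tagged with the total residue
    count of the database that was searched (the m8e header value)."""

    hits: tuple[AlignmentHit, ...] = ()
    db_length: Optional[int] = None
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "hits", tuple(self.hits))
        if self.db_length is not None and self.db_length < 1:
            raise ValueError("db_length must be >= 1 when present")

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[AlignmentHit]:
        return iter(self.hits)

    def query_ids(self) -> set[str]:
        return {h.query_id for h in self.hits}


# ---------------------------------------------------------------------------
# parsing


def _parse_row(line: str, lineno: int) -> AlignmentHit:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 12:
        raise M8FormatError(
            f"line {lineno}: expected 12 tab-separated fields, got {len(fields)}"
        )
    try:
        return AlignmentHit(
            query_id=fields[0],
            subject_id=fields[1],
            percent_identity=float(fields[2]),
            alignment_length=int(fields[3]),
            mismatches=int(fields[4]),
            gap_opens=int(fields[5]),
            q_start=int(fields[6]),
            q_end=int(fields[7]),
            s_start=int(fields[8]),
            s_end=int(fields[9]),
            evalue=float(fields[10]),
            bit_score=float(fields[11]),
        )
    except ValueError as exc:
        raise M8FormatError(f"line {lineno}: {exc}") from exc


def parse_result_table(
    stream: Union[IO[str], str],
    dialect: Dialect = "auto",
    source_label: str = "",
) -> ResultTable:
    """Parse an m8 or m8e stream into a :class:`ResultTable`.

    ``dialect='auto'`` resolves to m8e iff the first line is a valid header
    (a bare decimal integer, or ``#db_length:<int>``), else to m8.  Comment
    lines starting with ``#`` (other than a leading header of that form) are
    skipped, mirroring BLAST ``-outfmt 7`` tolerance.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()

    db_length: Optional[int] = None
    start = 0
    header_match = _HEADER_RE.match(lines[0]) if lines else None
    if dialect == "m8e":
        if header_match is None:
            raise M8FormatError("m8e requested but first line is not a valid header")
        db_length = int(header_match.group(1))
        if db_length < 1:
            raise M8FormatError("m8e header database length must be >= 1")
        start = 1
    elif dialect == "auto":
        if header_match is not None and int(header_match.group(1)) >= 1:
            db_length = int(header_match.group(1))
            start = 1
    elif dialect != "m8":
        raise ValueError(f"unknown dialect {dialect!r}")

    hits = []
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        hits.append(_parse_row(line, i))
    return ResultTable(hits=tuple(hits), db_length=db_length, source_label=source_label)


# ---------------------------------------------------------------------------
# writing


def _fmt_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    # shortest exact scientific form, at least 2 significant digits
    s = np.format_float_scientific(e, unique=True, trim="0")
    return s


def _fmt_float(x: float) -> str:
    # shortest exact positional form with at least one decimal place
    s = np.format_float_positional(x, unique=True, trim="0")
    return s


def _format_row(h: AlignmentHit) -> str:
    return "\t".join(
        [
            h.query_id,
            h.subject_id,
            _fmt_float(h.percent_identity),
            str(h.alignment_length),
            str(h.mismatches),
            str(h.gap_opens),
            str(h.q_start),
            str(h.q_end),
            str(h.s_start),
            str(h.s_end),
            _fmt_evalue(h.evalue),
            _fmt_float(h.bit_score),
        ]
    )


def write_result_table(table: ResultTable, dialect: Literal["m8", "m8e"] = "m8e") -> str:
    """Serialize a table to m8 or m8e text.

    The output re-parses to a field-equal table.  Writing m8e requires
    ``db_length``; writing m8 simply omits the header.
    """
    if dialect == "m8e":
        if table.db_length is None:
            raise ValueError("cannot write m8e: table has no db_length")
        out = [str(table.db_length)]
    elif dialect == "m8":
        out = []
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.extend(_format_row(h) for h in table.hits)
    return "\n".join(out) + "\n" if out else ""


def read_result_table(path, dialect: Dialect = "auto", source_label: str = "") -> ResultTable:
    with open(path) as fh:
        label = source_label or str(path)
        return parse_result_table(fh, dialect=dialect, source_label=label)


def save_result_table(table: ResultTable, path, dialect: Literal["m8", "m8e"] = "m8e") -> None:
    with open(path, "w") as fh:
        fh.write(write_result_table(table, dialect=dialect))


# ---------------------------------------------------------------------------
# database length


def attach_db_length(table: ResultTable, length: int) -> ResultTable:
    """Promote an m8 table to m8e semantics (or overwrite an existing length)."""
    if length < 1:
        raise ValueError("db_length must be >= 1")
    return replace(table, db_length=int(length))


def compute_db_length(fasta: Union[IO[str], str]) -> int:
    """Total residue count over all records of a FASTA database.

    This is the quantity the m8e header carries: Karlin-Altschul e-values
    scale with search-space residues, not with the number of sequences.
    """
    if isinstance(fasta, str) and "\n" not in fasta and not fasta.lstrip().startswith(">"):
        # a path
        with open(fasta) as fh:
            return compute_db_length(fh)
    if isinstance(fasta, str):
        fasta = io.StringIO(fasta)
    text = fasta.read()
    if text.lstrip() and not text.lstrip().startswith(">"):
        raise M8FormatError("malformed FASTA: does not start with '>'")
    total = 0
    n_records = 0
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        total += len(record.seq)
        n_records += 1
    if n_records == 0:
        raise ValueError("empty FASTA: a database must contain at least one record")
    return total
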