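"""Orchestration of the growing-database workflow.

A search state is just the merged result table with its cumulative database
length (m8e semantics): each new batch is searched on its own, and the batch
result is folded in by the merge.  Persisting the state is therefore nothing
more than writing the merged table as an m8e file, which makes the workflow
restartable with no bespoke state format.

External tools (blastp, mmseqs2, diamond) are driven through thin adapters
that request 12-column tabular output; any search tool that emits m8 rows can
be slotted in.  The in-package toy engine serves as a deterministic stand-in.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import yaml

from .m8io import ResultTable, attach_db_length, compute_db_length, parse_result_table, read_result_table, save_result_table
from .merge_engine import (
    DEFAULT_THRESHOLD,
    cap_hits_per_query,
    filter_threshold,
    merge_tables,
    sort_hits,
)
from .synthetic_search import ToyScoringParams, toy_search

__all__ = [
    "BatchState",
    "init_state",
    "add_batch",
    "run_external_search",
    "finalize",
    "save_state",
    "load_state",
    "load_config",
    "ToolNotFoundError",
    "SearchToolError",
]

logger = logging.getLogger(__name__)


class ToolNotFoundError(RuntimeError):
    """An external search tool is not installed / not on PATH."""


class SearchToolError(RuntimeError):
    """An external search tool exited with a failure."""


@dataclass(frozen=True)
class BatchState:
    """Accumulated incremental-search state.

    ``merged`` is the cumulative merged table; before any batch has been
    added it is empty with no db_length (cumulative length conceptually
    zero).  Value semantics: operations return new states and never mutate
    their input.
    """

    merged: ResultTable
    batches_processed: int
    tool_label: str

    @property
    def cumulative_db_length(self) -> int:
        return self.merged.db_length or 0


def init_state(tool_label: str = "") -> BatchState:
    return BatchState(merged=ResultTable(), batches_processed=0, tool_label=tool_label)


def add_batch(state: BatchState, batch_result: ResultTable) -> BatchState:
    """Fold one batch's search result into the state.

    The first batch becomes the merged table itself (re-sorted; rescaling to
    its own length is the identity); later batches go through the full merge,
    which inflates all previous e-values by the database growth factor.
    """
    if batch_result.db_length is None:
        raise ValueError(
            f"batch result {batch_result.source_label or '<unlabeled>'} has no "
            "db_length; promote it with attach_db_length first"
        )
    if state.batches_processed == 0:
        merged = replace(batch_result, hits=sort_hits(batch_result.hits))
    else:
        merged = merge_tables([state.merged, batch_result])
    logger.info(
        "batch %d added: +%d residues -> cumulative %d, %d hits",
        state.batches_processed + 1,
        batch_result.db_length,
        merged.db_length,
        len(merged),
    )
    return BatchState(
        merged=merged,
        batches_processed=state.batches_processed + 1,
        tool_label=state.tool_label,
    )


def finalize(
    state: BatchState,
    threshold: float = DEFAULT_THRESHOLD,
    cap: Optional[int] = None,
) -> ResultTable:
    """Produce the report table: sorted, thresholded, optionally capped.

    Filtering happens only here, never on the persisted state — rescaling
    only increases e-values, so keeping the full state preserves hits for
    ratio analyses and keeps the merge order-independent.
    """
    if state.batches_processed == 0:
        return state.merged
    table = replace(state.merged, hits=sort_hits(state.merged.hits))
    return cap_hits_per_query(filter_threshold(table, threshold), cap)


def save_state(state: BatchState, path) -> None:
    """Persist the state as a plain m8e file."""
    if state.batches_processed == 0:
        raise ValueError("cannot persist an empty state (no db_length yet)")
    save_result_table(state.merged, path, dialect="m8e")


def load_state(path, tool_label: str = "") -> BatchState:
    """Reload a persisted state.  The batch counter restarts at 1 (the m8e
    file consolidates all previously processed batches into one)."""
    merged = read_result_table(path, dialect="m8e")
    return BatchState(merged=merged, batches_processed=1, tool_label=tool_label)


# ---------------------------------------------------------------------------
# external tools


def _build_command(tool: str, query: str, db: str, out: str, threads: int, tool_path: str):
    """Command line for a 12-column tabular search with default parameters."""
    if tool == "blastp":
        return [tool_path, "-query", query, "-subject", db, "-outfmt", "6",
                "-out", out, "-num_threads", str(threads)]
    if tool == "mmseqs2":
        tmp = out + ".tmp"
        return [tool_path, "easy-search", query, db, out, tmp,
                "--threads", str(threads)]
    if tool == "diamond":
        return [tool_path, "blastp", "--query", query, "--db", db,
                "--outfmt", "6", "--out", out, "--threads", str(threads)]
    raise ValueError(f"unknown tool {tool!r}")


_TOOL_BINARIES = {"blastp": "blastp", "mmseqs2": "mmseqs", "diamond": "diamond"}


def run_external_search(
    tool: str,
    query_fasta,
    db_fasta,
    threads: int = 1,
    tool_path: Optional[str] = None,
    toy_params: Optional[ToyScoringParams] = None,
) -> ResultTable:
    """Search a query set against one database batch and return an m8e table.

    ``tool='toy'`` dispatches to the in-package engine; the real tools are
    invoked with their default parameters and 12-column tabular output.  The
    returned table carries the batch database length computed from the FASTA,
    ready for :func:`add_batch`.
    """
    query_fasta, db_fasta = str(query_fasta), str(db_fasta)
    if not Path(query_fasta).exists():
        raise FileNotFoundError(f"query FASTA not found: {query_fasta}")
    if not Path(db_fasta).exists():
        raise FileNotFoundError(f"database FASTA not found: {db_fasta}")
    db_len = compute_db_length(db_fasta)  # raises on empty database

    if tool == "toy":
        return toy_search(query_fasta, db_fasta, toy_params or ToyScoringParams())

    binary = _TOOL_BINARIES.get(tool)
    if binary is None:
        raise ValueError(f"unknown tool {tool!r}")
    resolved = tool_path or shutil.which(binary)
    if resolved is None:
        raise ToolNotFoundError(
            f"{binary} not found on PATH; install it or pass tool_path= "
            f"(or set tool_paths.{tool} in the config file)"
        )
    with tempfile.TemporaryDirectory() as tmpdir:
        out = str(Path(tmpdir) / "result.m8")
        cmd = _build_command(tool, query_fasta, db_fasta, out, threads, resolved)
        logger.info("running: %s", " ".join(cmd))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise SearchToolError(
                f"{tool} exited with status {proc.returncode}\n"
                f"command: {' '.join(cmd)}\nstderr:\n{proc.stderr}"
            )
        with open(out) as fh:
            table = parse_result_table(fh, dialect="m8", source_label=db_fasta)
    return attach_db_length(table, db_len)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG = {
    "tool_paths": {},          # e.g. {"mmseqs2": "/opt/mmseqs/bin/mmseqs"}
    "threshold": DEFAULT_THRESHOLD,
    "log_level": "INFO",
}


def load_config(path=None) -> dict:
    """Key-value YAML config: tool paths, default threshold, log verbosity."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a YAML mapping")
        cfg.update(user)
    logging.getLogger("incseq").setLevel(cfg.get("log_level", "INFO"))
    return cfg
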