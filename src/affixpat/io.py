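"""FASTA input and delimited results output.

Target records are normalized on the way in: uppercased, T converted to U,
and every non-ACGU character collapsed to the single wildcard placeholder
``#`` (all such characters behave identically: they satisfy no query
code).  Results go out as TSV/CSV with one row per match, importable into
any spreadsheet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .esa import normalize_seq
from .results import Match

__all__ = ["TargetRecord", "FastaError", "read_fasta", "write_matches", "matches_frame"]

#: mirrors the 100 MB upload limit of the original service
DEFAULT_SIZE_LIMIT = 100 * 1024 * 1024

RESULT_COLUMNS = [
    "target_id",
    "start",
    "end",
    "matched_seq",
    "aligned_structure",
    "gap_total",
    "gap_vector",
    "cost",
]


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class TargetRecord:
    """One normalized FASTA record."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


def read_fasta(path, size_limit: int = DEFAULT_SIZE_LIMIT) -> list[TargetRecord]:
    """Read and normalize a (multi-record, possibly line-wrapped) FASTA file."""
    size = os.path.getsize(path)
    if size > size_limit:
        raise FastaError(
            f"{path} is {size} bytes; the limit is {size_limit} "
            "(raise size_limit to override)"
        )
    with open(path) as fh:
        head = fh.read(1024)
    stripped = head.lstrip()
    if not stripped:
        raise FastaError(f"{path} is empty")
    if not stripped.startswith(">"):
        raise FastaError(f"{path}: sequence data before any FASTA header")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise FastaError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_seq(str(rec.seq))
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(TargetRecord(id=rec.id, seq=seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def matches_frame(matches: Sequence[Match]) -> pd.DataFrame:
    """Results table with one row per match."""
    return pd.DataFrame(
        [
            {
                "target_id": m.target_id,
                "start": m.start,
                "end": m.end,
                "matched_seq": m.matched_seq,
                "aligned_structure": m.realized_struct,
                "gap_total": m.gap_total,
                "gap_vector": ",".join(map(str, m.gap_lengths)),
                "cost": m.cost,
            }
            for m in matches
        ],
        columns=RESULT_COLUMNS,
    )


def write_matches(
    matches: Sequence[Match],
    path,
    format: str = "tsv",
    sort_by: str | None = None,
) -> None:
    """Write matches as delimited text (header always included).

    ``sort_by`` re-sorts rows by ``start``, ``gap_total`` or ``cost``
    (stable, so the canonical order breaks ties).
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown output format {format!r}")
    df = matches_frame(matches)
    if sort_by is not None:
        if sort_by not in ("start", "gap_total", "cost"):
            raise ValueError(f"cannot sort by {sort_by!r}")
        df = df.sort_values(sort_by, kind="stable")
    df.to_csv(path, sep="\t" if format == "tsv" else ",", index=False)
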