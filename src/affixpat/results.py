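"""Match records and the layout of a query over a concrete target span.

Shared by the affix-array engine and the brute-force reference matcher so
the two code paths emit directly comparable results while sharing no search
logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .query import Query

__all__ = ["Match", "element_layout", "realize_structure", "sort_matches", "collapse_matches"]


@dataclass(frozen=True)
class Match:
    """One reported occurrence of a query in a target record.

    ``start``/``end`` are 1-based inclusive positions in the target;
    ``gap_lengths`` lists the realized length of every variable gap slot in
    query order; ``cost`` is the sum of pairing-matrix costs over all
    realized base pairs.
    """

    target_id: str
    start: int
    end: int
    matched_seq: str
    realized_struct: str
    gap_lengths: tuple[int, ...]
    gap_total: int
    cost: float

    def key(self) -> tuple:
        """Identity used for deduplication and cross-engine comparison."""
        return (self.target_id, self.start, self.end, self.gap_lengths, self.cost)


def element_layout(q: Query, gap_vec: Sequence[int]) -> list[tuple[int, int]]:
    """Per-element (offset, length) within a match span for one gap vector.

    Fixed elements have length 1, gap slots their realized length.  Offsets
    are relative to the match start.
    """
    if len(gap_vec) != len(q.gap_slots):
        raise ValueError("gap vector length does not match the query's gap slots")
    layout = []
    off = 0
    slot = 0
    for e in q.seq:
        if e.kind == "gap":
            length = int(gap_vec[slot])
            if not 0 <= length <= e.max_len:
                raise ValueError("gap length outside the slot's bound")
            slot += 1
        else:
            length = 1
        layout.append((off, length))
        off += length
    return layout


def realize_structure(q: Query, gap_vec: Sequence[int]) -> str:
    """Structure string with every gap expanded to its realized dots."""
    sym = {"dot": ".", "open": "(", "close": ")"}
    parts = []
    slot = 0
    for e in q.struct:
        if e.kind == "gap":
            parts.append("." * int(gap_vec[slot]))
            slot += 1
        else:
            parts.append(sym[e.kind])
    return "".join(parts)


def sort_matches(matches: list[Match]) -> list[Match]:
    """Canonical report order: target, start, fewest gaps first."""
    return sorted(
        matches,
        key=lambda m: (m.target_id, m.start, m.gap_total, m.gap_lengths, m.end),
    )


def collapse_matches(matches: list[Match]) -> list[Match]:
    """Keep one match per (target, span): the minimum gap_total, ties going
    to the lexicographically smallest gap vector."""
    best: dict[tuple[str, int, int], Match] = {}
    for m in matches:
        k = (m.target_id, m.start, m.end)
        cur = best.get(k)
        if cur is None or (m.gap_total, m.gap_lengths) < (cur.gap_total, cur.gap_lengths):
            best[k] = m
    return sort_matches(list(best.values()))
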