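"""Brute-force reference matcher defining the ground-truth match semantics.

For every start position and every gap-length vector in the Cartesian
product of the slots' ranges, the query is laid over the target and every
constraint checked directly: fixed positions against their IUPAC codes,
every covered position against the no-wildcard rule, every bracket pair
against the cost matrix.  No index, no decomposition, no cleverness — a
completely different code path from the affix-array engine, which is what
makes agreement between the two meaningful evidence of correctness.

Deliberately quadratic-ish; a work-limit guard refuses inputs too large to
enumerate.  Shares only the query model and the Match record with the
engine.
"""

from __future__ import annotations

import itertools
import math

from .query import IUPAC_EXPANSION, PairingMatrix, Query
from .results import Match, element_layout, realize_structure, sort_matches

__all__ = ["oracle_search", "check_candidate", "WorkLimitExceeded", "DEFAULT_WORK_LIMIT"]

DEFAULT_WORK_LIMIT = 20_000_000


class WorkLimitExceeded(ValueError):
    """The instance is too large for exhaustive enumeration."""


def check_candidate(
    seq: str, q: Query, matrix: PairingMatrix, start: int, gap_vec: tuple[int, ...]
) -> float | None:
    """Check one (start, gap vector) candidate on a normalized target.

    Returns the total pairing cost when every constraint holds, else None.
    ``start`` is 0-based; ``seq`` must be normalized (ACGU + ``#``).
    """
    layout = element_layout(q, gap_vec)
    span = layout[-1][0] + layout[-1][1]
    if start < 0 or start + span > len(seq):
        return None
    window = seq[start : start + span]
    if "#" in window:  # wildcards satisfy nothing, gaps included
        return None
    for e, (off, _length) in zip(q.seq, layout):
        if e.kind == "code" and window[off] not in IUPAC_EXPANSION[e.code]:
            return None
    cost = 0.0
    for i, j in q.pairs:
        c = matrix.cost[(window[layout[i][0]], window[layout[j][0]])]
        if math.isinf(c):
            return None
        cost += c
    return cost


def oracle_search(
    target_id: str,
    seq: str,
    q: Query,
    matrix: PairingMatrix,
    work_limit: int = DEFAULT_WORK_LIMIT,
) -> list[Match]:
    """All matches of the query in one normalized target, exhaustively.

    Output is canonical: sorted by start position, then gap vector.
    """
    n = len(seq)
    n_vectors = 1
    for slot in q.gap_slots:
        n_vectors *= q.seq[slot].max_len + 1
    if (n + 1) * n_vectors > work_limit:
        raise WorkLimitExceeded(
            f"{n + 1} starts x {n_vectors} gap vectors exceeds work limit {work_limit}"
        )
    matches: list[Match] = []
    ranges = [range(q.seq[slot].max_len + 1) for slot in q.gap_slots]
    for gap_vec in itertools.product(*ranges):
        span = q.fixed_len + sum(gap_vec)
        struct = realize_structure(q, gap_vec)
        for start in range(n - span + 1):
            cost = check_candidate(seq, q, matrix, start, gap_vec)
            if cost is not None:
                matches.append(
                    Match(
                        target_id=target_id,
                        start=start + 1,
                        end=start + span,
                        matched_seq=seq[start : start + span],
                        realized_struct=struct,
                        gap_lengths=tuple(gap_vec),
                        gap_total=sum(gap_vec),
                        cost=cost,
                    )
                )
    return sort_matches(matches)
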