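"""Affix-array search engine for combined sequence/structure queries.

The pipeline, in the order it runs:

1. :func:`decompose_query` splits the query structure into hairpin-like
   sections — maximal unbranched stem-loops, each containing exactly one
   innermost loop — plus a remainder (external dots/gaps and
   multiloop-closing stems).
2. Sections are searched most-specific-first (:func:`specificity_rank`),
   each with :func:`bidirectional_search`: matching starts from the loop
   and alternates outward, testing each closing base immediately after its
   opening base, hopping between the forward and reverse-prefix arrays via
   affix links.  Variable gaps branch over their realized lengths; repeated
   subproblems (same remaining sub-query, same interval) are solved once
   through a memoized task table.
3. :func:`merge_sections` assembles section matches under the distance
   window implied by the fixed elements and gap bounds between sections.
4. :func:`verify_remainder` lays the non-hairpin remainder over each
   assembly, enumerating admissible remainder gap lengths and checking
   sequence codes and any remainder base pairs directly.

Pairing constraints always apply to the two concrete target bases; costs
are accumulated additively from the pairing matrix.  Targets are searched
one record at a time on the forward strand.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .affix import FWD, REV, AffixArray, build_affix_array
from .esa import CODE_OF, Interval
from .query import IUPAC_EXPANSION, PairingMatrix, Query, default_pairing_matrix
from .results import Match, realize_structure, sort_matches, collapse_matches

__all__ = [
    "HairpinSection",
    "SectionMatch",
    "decompose_query",
    "specificity_rank",
    "bidirectional_search",
    "merge_sections",
    "verify_remainder",
    "search",
]

_ACGU_CODES = tuple(CODE_OF[b] for b in "ACGU")
_BASE_CODE = {b: CODE_OF[b] for b in "ACGU"}
_CODE_BASE = {v: k for k, v in _BASE_CODE.items()}


@dataclass(frozen=True)
class HairpinSection:
    """A contiguous query interval holding one unbranched stem-loop."""

    start: int  # element indices, inclusive
    end: int
    loop: tuple[int, int]  # inclusive run of unpaired loop elements; empty if loop[0] > loop[1]
    pairs: tuple[tuple[int, int], ...]
    gap_slots: tuple[int, ...]
    specificity: int = 0


@dataclass(frozen=True)
class SectionMatch:
    """One placement of a section on the target (0-based half-open span)."""

    start: int
    end: int
    gaps: tuple[tuple[int, int], ...]  # (gap element index, realized length)
    cost: float


def decompose_query(q: Query) -> tuple[list[HairpinSection], list[tuple[int, int]]]:
    """Split a query into hairpin-like sections and the remainder.

    Each innermost bracket pair seeds a section; the stem grows outward
    through consecutive pairs as long as the enclosing pair has a single
    branch, stopping at any branching point.  The remainder is the list of
    maximal element ranges not covered by a section.
    """
    pairs = sorted(q.pairs)
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            parent[p] = stack[-1]
            children[stack[-1]].append(p)
        stack.append(p)

    sections: list[HairpinSection] = []
    for p in pairs:
        if children[p]:
            continue  # not innermost
        inner = p
        cur = p
        while cur in parent and len(children[parent[cur]]) == 1:
            cur = parent[cur]
        a, b = cur
        sec_pairs = tuple(pp for pp in pairs if a <= pp[0] and pp[1] <= b)
        gap_slots = tuple(i for i in q.gap_slots if a <= i <= b)
        sec = HairpinSection(
            start=a,
            end=b,
            loop=(inner[0] + 1, inner[1] - 1),
            pairs=sec_pairs,
            gap_slots=gap_slots,
        )
        sections.append(
            HairpinSection(**{**sec.__dict__, "specificity": specificity_rank(sec, q)})
        )
    sections.sort(key=lambda s: s.start)

    remainder: list[tuple[int, int]] = []
    pos = 0
    for s in sections:
        if pos < s.start:
            remainder.append((pos, s.start - 1))
        pos = s.end + 1
    if pos < len(q):
        remainder.append((pos, len(q) - 1))
    return sections, remainder


def specificity_rank(section: HairpinSection, q: Query) -> int:
    """Lower is more specific: degenerate positions count 1 each, every gap
    its full bound (gap-heavy sections are searched later)."""
    score = 0
    for i in range(section.start, section.end + 1):
        e = q.seq[i]
        if e.kind == "gap":
            score += e.max_len
        elif len(IUPAC_EXPANSION[e.code]) > 1:
            score += 1
    return score


def _section_order(sections: list[HairpinSection], q: Query) -> list[int]:
    """Indices into ``sections`` in search order: most specific first,
    longer section winning ties, then leftmost."""
    return sorted(
        range(len(sections)),
        key=lambda i: (
            sections[i].specificity,
            -(sections[i].end - sections[i].start + 1),
            sections[i].start,
        ),
    )


class _BidiState:
    """Shared machinery for interval walking over one affix array."""

    def __init__(self, afx: AffixArray):
        self.afx = afx

    def root(self, direction: str) -> tuple[str, int, int, int]:
        esa = self.afx.esa(direction)
        return (direction, 0, esa.n - 1, 0)

    def to_dir(self, state, direction):
        d, lo, hi, depth = state
        if depth == 0:
            return self.root(direction)
        if d == direction:
            return state
        iv = self.afx.affix_link(d, Interval(lo, hi, depth))
        return (direction, iv.lo, iv.hi, iv.depth)

    def extend(self, state, direction, c):
        """Grow the matched word by character c on the given side."""
        s = self.to_dir(state, direction)
        iv = self.afx.esa(direction).interval_extend(Interval(s[1], s[2], s[3]), c)
        if iv is None:
            return None
        return (direction, iv.lo, iv.hi, iv.depth)

    def positions(self, state):
        d, lo, hi, depth = state
        return self.afx.positions(d, Interval(lo, hi, depth)), depth


def bidirectional_search(
    afx: AffixArray, section: HairpinSection, q: Query, matrix: PairingMatrix
) -> list[SectionMatch]:
    """All placements of one hairpin section on the indexed target.

    The traversal starts inside the loop (plain rightward extension), then
    alternates outward through the stem: the opening (5') base extends the
    word leftward on the reverse-prefix array, and its closing base is
    tested immediately after by a rightward extension, keeping only base
    combinations with finite pairing cost.  Gap slots branch over realized
    lengths 0..bound, each consumed position being any concrete base.
    Subproblems are memoized by (next left element, next right element,
    interval state); realized gap lengths live outside the memo so distinct
    gap splits are never conflated.
    """
    bidi = _BidiState(afx)
    struct, seq = q.struct, q.seq
    expansions = {
        i: tuple(sorted(_BASE_CODE[b] for b in IUPAC_EXPANSION[seq[i].code]))
        for i in range(section.start, section.end + 1)
        if seq[i].kind == "code"
    }
    allowed = {}
    for (b1, b2), c in matrix.cost.items():
        if c != float("inf"):
            allowed.setdefault(_BASE_CODE[b1], []).append((_BASE_CODE[b2], c))

    def gap_branches(state, direction, bound):
        """All (length, state) reachable by consuming 0..bound free bases."""
        out = [(0, state)]
        frontier = [state]
        for k in range(1, bound + 1):
            nxt = []
            for s in frontier:
                for c in _ACGU_CODES:
                    s2 = bidi.extend(s, direction, c)
                    if s2 is not None:
                        nxt.append(s2)
            frontier = nxt
            out.extend((k, s) for s in frontier)
            if not frontier:
                break
        return out

    # ---- phase 1: the loop, left to right -------------------------------
    loop_states: list[tuple[tuple, tuple[tuple[int, int], ...]]] = []

    def walk_loop(idx, state, gaps):
        if idx > section.loop[1]:
            loop_states.append((state, gaps))
            return
        e = seq[idx]
        if e.kind == "gap":
            for k, s2 in gap_branches(state, FWD, e.max_len):
                walk_loop(idx + 1, s2, gaps + ((idx, k),))
        else:
            for c in expansions[idx]:
                s2 = bidi.extend(state, FWD, c)
                if s2 is not None:
                    walk_loop(idx + 1, s2, gaps)

    walk_loop(section.loop[0], bidi.root(FWD), ())
    if not loop_states:
        return []

    # ---- phase 2: the stem, alternating outward -------------------------
    memo: dict[tuple, list[tuple[tuple, tuple, float]]] = {}

    def step(lp, rp, state):
        """Outcomes of finishing the section from (lp, rp): list of
        (final state, gap assignments for remaining slots, added cost)."""
        if lp < section.start and rp > section.end:
            return [(state, (), 0.0)]
        key = (lp, rp, state)
        hit = memo.get(key)
        if hit is not None:
            return hit
        out = []
        if lp >= section.start and struct[lp].kind in ("dot", "gap"):
            e = seq[lp]
            if e.kind == "gap":
                for k, s2 in gap_branches(state, REV, e.max_len):
                    for fs, g, c in step(lp - 1, rp, s2):
                        out.append((fs, g + ((lp, k),), c))
            else:
                for c0 in expansions[lp]:
                    s2 = bidi.extend(state, REV, c0)
                    if s2 is not None:
                        out.extend(step(lp - 1, rp, s2))
        elif rp <= section.end and struct[rp].kind in ("dot", "gap"):
            e = seq[rp]
            if e.kind == "gap":
                for k, s2 in gap_branches(state, FWD, e.max_len):
                    for fs, g, c in step(lp, rp + 1, s2):
                        out.append((fs, g + ((rp, k),), c))
            else:
                for c0 in expansions[rp]:
                    s2 = bidi.extend(state, FWD, c0)
                    if s2 is not None:
                        out.extend(step(lp, rp + 1, s2))
        else:
            # both sides sit on the brackets of one stem pair
            for b1 in expansions[lp]:
                s1 = bidi.extend(state, REV, b1)
                if s1 is None:
                    continue
                for b2, pc in allowed.get(b1, ()):
                    if b2 not in expansions[rp]:
                        continue
                    s2 = bidi.extend(s1, FWD, b2)
                    if s2 is None:
                        continue
                    for fs, g, c in step(lp - 1, rp + 1, s2):
                        out.append((fs, g, c + pc))
        memo[key] = out
        return out

    matches: list[SectionMatch] = []
    for state, loop_gaps, in loop_states:
        for fs, stem_gaps, cost in step(section.loop[0] - 1, section.loop[1] + 1, state):
            positions, depth = bidi.positions(fs)
            gaps = tuple(sorted(loop_gaps + stem_gaps))
            for pos in positions:
                matches.append(
                    SectionMatch(int(pos), int(pos) + depth, gaps, cost)
                )
    return matches


# ---------------------------------------------------------------------------
# assembling sections and verifying the remainder
# ---------------------------------------------------------------------------


@dataclass
class _Geometry:
    """Prefix sums of fixed-element counts and gap bounds over the query."""

    fixed: list[int]  # fixed[i] = # non-gap elements among 0..i-1
    bound: list[int]  # bound[i] = sum of gap bounds among 0..i-1

    @classmethod
    def of(cls, q: Query) -> "_Geometry":
        fixed, bound = [0], [0]
        for e in q.seq:
            fixed.append(fixed[-1] + (e.kind != "gap"))
            bound.append(bound[-1] + (e.max_len if e.kind == "gap" else 0))
        return cls(fixed, bound)

    def span_range(self, a: int, b: int) -> tuple[int, int]:
        """Min/max target length of query elements a..b-1 (half-open)."""
        lo = self.fixed[b] - self.fixed[a]
        return lo, lo + self.bound[b] - self.bound[a]


def merge_sections(
    assemblies: list[dict[int, SectionMatch]] | None,
    new_matches: list[SectionMatch],
    sec_index: int,
    sections: list[HairpinSection],
    q: Query,
    target_len: int,
    geom: _Geometry | None = None,
) -> list[dict[int, SectionMatch]]:
    """Place one more section into each partial assembly.

    A placement survives when the target distance to the nearest placed
    section on each side lies inside [min, max] of the span of the query
    elements between them (fixed elements plus bounded gaps, including any
    not-yet-placed sections), and when enough target remains for the query
    prefix/suffix outside the outermost placed sections.  New matches are
    sorted by the index facing the already-placed neighbour and candidates
    located by binary search.
    """
    geom = geom or _Geometry.of(q)
    sec = sections[sec_index]
    pre_min, _ = geom.span_range(0, sec.start)
    suf_min, _ = geom.span_range(sec.end + 1, len(q))

    feasible = [
        m
        for m in new_matches
        if m.start >= pre_min and target_len - m.end >= suf_min
    ]
    if assemblies is None:
        return [{sec_index: m} for m in feasible]

    by_start = sorted(feasible, key=lambda m: m.start)
    starts = [m.start for m in by_start]
    by_end = sorted(feasible, key=lambda m: m.end)
    ends = [m.end for m in by_end]

    out: list[dict[int, SectionMatch]] = []
    for asm in assemblies:
        left = max((i for i in asm if i < sec_index), default=None)
        right = min((i for i in asm if i > sec_index), default=None)
        if left is not None:
            lm = asm[left]
            lo, hi = geom.span_range(sections[left].end + 1, sec.start)
            cands = by_start[
                bisect_left(starts, lm.end + lo) : bisect_right(starts, lm.end + hi)
            ]
        elif right is not None:
            rm = asm[right]
            lo, hi = geom.span_range(sec.end + 1, sections[right].start)
            cands = by_end[
                bisect_left(ends, rm.start - hi) : bisect_right(ends, rm.start - lo)
            ]
        else:
            cands = feasible
        for m in cands:
            if left is not None and right is not None:
                rm = asm[right]
                lo2, hi2 = geom.span_range(sec.end + 1, sections[right].start)
                if not lo2 <= rm.start - m.end <= hi2:
                    continue
            out.append({**asm, sec_index: m})
    return out


def _compositions(total: int, bounds: list[int]):
    """All ways to write ``total`` as bounded non-negative parts."""
    if not bounds:
        if total == 0:
            yield ()
        return
    head = bounds[0]
    rest = bounds[1:]
    rest_max = sum(rest)
    for k in range(max(0, total - rest_max), min(head, total) + 1):
        for tail in _compositions(total - k, rest):
            yield (k,) + tail


def verify_remainder(
    target_id: str,
    seq: str,
    assembly: dict[int, SectionMatch],
    q: Query,
    matrix: PairingMatrix,
    sections: list[HairpinSection],
) -> list[Match]:
    """Expand one full-section assembly into complete matches.

    Enumerates every admissible assignment of remainder gap lengths (free
    at the query edges, sum-constrained between placed sections), checks
    remainder sequence codes and wildcard exclusion directly against the
    target, evaluates remainder bracket pairs (multiloop-closing stems)
    through the pairing matrix, and emits fully realized matches.
    """
    geom = _Geometry.of(q)
    order = sorted(assembly)  # query order; all sections placed
    n = len(seq)

    # regions: (kind, element range a..b half-open, anchor info)
    regions = []
    first = sections[order[0]]
    if first.start > 0:
        regions.append(("lead", 0, first.start))
    for u, v in zip(order, order[1:]):
        a, b = sections[u].end + 1, sections[v].start
        regions.append(("mid", a, b, assembly[u].end, assembly[v].start))
    last = sections[order[-1]]
    if last.end + 1 < len(q):
        regions.append(("trail", last.end + 1, len(q)))

    def region_assignments(region):
        """Yield (gap assignment dict, region target start) options."""
        kind, a, b = region[0], region[1], region[2]
        slots = [i for i in range(a, b) if q.seq[i].kind == "gap"]
        bounds = [q.seq[i].max_len for i in slots]
        f = sum(1 for i in range(a, b) if q.seq[i].kind != "gap")
        if kind == "mid":
            left_end, right_start = region[3], region[4]
            total = right_start - left_end - f
            if total < 0:
                return
            for comp in _compositions(total, bounds):
                yield dict(zip(slots, comp)), left_end
        elif kind == "lead":
            anchor = assembly[order[0]].start
            for comp in itertools.product(*(range(x + 1) for x in bounds)):
                start = anchor - f - sum(comp)
                if start >= 0:
                    yield dict(zip(slots, comp)), start
        else:  # trail
            anchor = assembly[order[-1]].end
            for comp in itertools.product(*(range(x + 1) for x in bounds)):
                if anchor + f + sum(comp) <= n:
                    yield dict(zip(slots, comp)), anchor

    section_cost = sum(m.cost for m in assembly.values())
    section_gaps: dict[int, int] = {}
    for m in assembly.values():
        section_gaps.update(dict(m.gaps))

    per_region = [list(region_assignments(r)) for r in regions]
    matches: list[Match] = []
    for combo in itertools.product(*per_region):
        gaps = dict(section_gaps)
        elem_pos: dict[int, int] = {}
        ok = True
        for region, (assign, rstart) in zip(regions, combo):
            gaps.update(assign)
            pos = rstart
            for i in range(region[1], region[2]):
                e = q.seq[i]
                if e.kind == "gap":
                    seg = seq[pos : pos + assign[i]]
                    if "#" in seg:
                        ok = False
                        break
                    pos += assign[i]
                else:
                    ch = seq[pos] if pos < n else "#"
                    if ch == "#" or ch not in IUPAC_EXPANSION[e.code]:
                        ok = False
                        break
                    elem_pos[i] = pos
                    pos += 1
            if not ok:
                break
        if not ok:
            continue
        cost = section_cost
        for i, j in q.pairs:
            if i in elem_pos:  # remainder pair; section pairs already costed
                c = matrix.cost[(seq[elem_pos[i]], seq[elem_pos[j]])]
                if c == float("inf"):
                    ok = False
                    break
                cost += c
        if not ok:
            continue
        # overall span
        if regions and regions[0][0] == "lead":
            start0 = combo[0][1]
        else:
            start0 = assembly[order[0]].start
        if regions and regions[-1][0] == "trail":
            assign, rstart = combo[-1]
            f = sum(
                1 for i in range(regions[-1][1], regions[-1][2]) if q.seq[i].kind != "gap"
            )
            end0 = rstart + f + sum(assign.values())
        else:
            end0 = assembly[order[-1]].end
        gap_vec = tuple(gaps[i] for i in q.gap_slots)
        matches.append(
            Match(
                target_id=target_id,
                start=start0 + 1,
                end=end0,
                matched_seq=seq[start0:end0],
                realized_struct=realize_structure(q, gap_vec),
                gap_lengths=gap_vec,
                gap_total=sum(gap_vec),
                cost=cost,
            )
        )
    return matches


def _forward_scan(
    afx: AffixArray, target_id: str, q: Query
) -> list[Match]:
    """Pair-free queries (all dots/gaps): plain forward interval search
    over the suffix array with the same gap branching."""
    bidi = _BidiState(afx)
    seq_text = afx.fwd.text[:-1]
    expansions = {
        i: tuple(sorted(_BASE_CODE[b] for b in IUPAC_EXPANSION[e.code]))
        for i, e in enumerate(q.seq)
        if e.kind == "code"
    }
    out: list[Match] = []

    def rec(idx, state, gaps):
        if idx == len(q):
            positions, depth = bidi.positions(state)
            gap_vec = tuple(k for _i, k in sorted(gaps))
            struct = realize_structure(q, gap_vec)
            for pos in positions:
                p = int(pos)
                out.append(
                    Match(
                        target_id=target_id,
                        start=p + 1,
                        end=p + depth,
                        matched_seq=seq_text[p : p + depth],
                        realized_struct=struct,
                        gap_lengths=gap_vec,
                        gap_total=sum(gap_vec),
                        cost=0.0,
                    )
                )
            return
        e = q.seq[idx]
        if e.kind == "gap":
            frontier = [state]
            for k in range(0, e.max_len + 1):
                if k > 0:
                    nxt = []
                    for s in frontier:
                        for c in _ACGU_CODES:
                            s2 = bidi.extend(s, FWD, c)
                            if s2 is not None:
                                nxt.append(s2)
                    frontier = nxt
                    if not frontier:
                        break
                for s in frontier:
                    rec(idx + 1, s, gaps + ((idx, k),))
        else:
            for c in expansions[idx]:
                s2 = bidi.extend(state, FWD, c)
                if s2 is not None:
                    rec(idx + 1, s2, gaps)

    rec(0, bidi.root(FWD), ())
    return out


def search_record(
    afx: AffixArray, target_id: str, q: Query, matrix: PairingMatrix
) -> list[Match]:
    """All matches of the query in one indexed target record."""
    sections, _remainder = decompose_query(q)
    seq = afx.fwd.text[:-1]
    if not sections:
        matches = _forward_scan(afx, target_id, q)
    else:
        geom = _Geometry.of(q)
        order = _section_order(sections, q)
        assemblies: list[dict[int, SectionMatch]] | None = None
        for sec_index in order:
            sm = bidirectional_search(afx, sections[sec_index], q, matrix)
            assemblies = merge_sections(
                assemblies, sm, sec_index, sections, q, len(seq), geom
            )
            if not assemblies:
                return []
        matches = []
        for asm in assemblies:
            matches.extend(
                verify_remainder(target_id, seq, asm, q, matrix, sections)
            )
    unique = {(m.target_id, m.start, m.gap_lengths): m for m in matches}
    return sort_matches(list(unique.values()))


def search(
    records,
    q: Query,
    matrix: PairingMatrix | None = None,
    collapse: bool = False,
    indexes: dict[str, AffixArray] | None = None,
) -> list[Match]:
    """Search every target record and pool the matches.

    ``records`` yields (id, sequence) pairs or objects with ``id``/``seq``
    attributes; sequences may be raw (normalization is applied when the
    index is built).  Prebuilt/cached affix arrays can be supplied via
    ``indexes`` keyed by record id.
    """
    matrix = matrix or default_pairing_matrix()
    all_matches: list[Match] = []
    for rec in records:
        rid, rseq = (rec.id, rec.seq) if hasattr(rec, "id") else rec
        afx = (indexes or {}).get(rid) or build_affix_array(rseq)
        all_matches.extend(search_record(afx, rid, q, matrix))
    out = sort_matches(all_matches)
    return collapse_matches(out) if collapse else out
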