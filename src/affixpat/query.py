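"""Combined RNA sequence/structure query language and base-pairing cost matrices.

A query is given as two aligned strings: a sequence pattern over IUPAC
nucleotide codes and a structure pattern in dot-bracket notation.  Both may
contain variable gaps written ``[x]``, each matching between 0 and ``x``
unconstrained, unpaired nucleotides; a gap must appear at the same position
with the same bound in both patterns.  Matched parentheses in the structure
pattern denote base-paired positions; the admissible pairs and their costs
come from a 4x4 :class:`PairingMatrix` over {A, C, G, U}.

Conventions applied throughout the package:

* T is normalized to U and letters are case-insensitive.
* Pairing constraints are evaluated on the two concrete target bases that
  occupy paired positions, never on the (possibly ambiguous) query codes,
  so the cost of a match does not depend on which IUPAC expansion matched.
* A target character outside {A, C, G, U} (an ``N`` or any other wildcard)
  matches no query code at all, including ``N`` in the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "SeqElement",
    "StructElement",
    "Query",
    "PairingMatrix",
    "QueryError",
    "IUPAC_EXPANSION",
    "parse_sequence_pattern",
    "parse_structure_pattern",
    "make_query",
    "parse_query",
    "parse_pairing_matrix",
    "default_pairing_matrix",
    "iupac_matches",
    "pair_cost",
    "render_sequence_pattern",
    "render_structure_pattern",
]

BASES = ("A", "C", "G", "U")

#: IUPAC degenerate nucleotide codes expanded over the RNA alphabet.
IUPAC_EXPANSION: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: Upper bound on any single gap's ``x`` to reject pathological queries.
DEFAULT_GAP_CAP = 10_000


class QueryError(ValueError):
    """Raised for malformed patterns, matrices or inconsistent queries."""


@dataclass(frozen=True)
class SeqElement:
    """One element of a sequence pattern: an IUPAC code or a variable gap."""

    kind: str  # "code" | "gap"
    code: str | None = None
    max_len: int = 0

    def __post_init__(self) -> None:
        if self.kind == "code":
            if self.code not in IUPAC_EXPANSION:
                raise QueryError(f"invalid IUPAC code {self.code!r}")
        elif self.kind == "gap":
            if self.max_len < 0:
                raise QueryError("gap bound must be non-negative")
        else:  # pragma: no cover - construction guard
            raise QueryError(f"unknown element kind {self.kind!r}")


@dataclass(frozen=True)
class StructElement:
    """One element of a structure pattern: dot, bracket or variable gap."""

    kind: str  # "dot" | "open" | "close" | "gap"
    max_len: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("dot", "open", "close", "gap"):  # pragma: no cover
            raise QueryError(f"unknown element kind {self.kind!r}")
        if self.kind == "gap" and self.max_len < 0:
            raise QueryError("gap bound must be non-negative")


@dataclass(frozen=True)
class Query:
    """A validated combined sequence/structure pattern.

    ``pairs`` holds the element-index pairs induced by bracket matching,
    ``gap_slots`` the element indices of variable gaps in textual order.
    """

    seq: tuple[SeqElement, ...]
    struct: tuple[StructElement, ...]
    pairs: tuple[tuple[int, int], ...]
    gap_slots: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def fixed_len(self) -> int:
        """Number of non-gap elements (the minimum match span)."""
        return sum(1 for e in self.seq if e.kind != "gap")

    @property
    def max_gap_total(self) -> int:
        return sum(self.seq[i].max_len for i in self.gap_slots)

    @property
    def max_span(self) -> int:
        return self.fixed_len + self.max_gap_total


class PairingMatrix:
    """Cost per ordered base pair over {A, C, G, U}; ``inf`` disallows a pair."""

    __slots__ = ("cost", "allowed_pairs")

    def __init__(self, cost: Mapping[tuple[str, str], float]):
        for b1 in BASES:
            for b2 in BASES:
                if (b1, b2) not in cost:
                    raise QueryError(f"matrix entry missing for pair {b1}{b2}")
                if cost[(b1, b2)] < 0:
                    raise QueryError(f"negative cost for pair {b1}{b2}")
        self.cost = {(b1, b2): float(cost[(b1, b2)]) for b1 in BASES for b2 in BASES}
        self.allowed_pairs = tuple(
            p for p in self.cost if math.isfinite(self.cost[p])
        )
        if not self.allowed_pairs:
            raise QueryError("matrix allows no base pair at all")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairingMatrix) and self.cost == other.cost


def default_pairing_matrix() -> PairingMatrix:
    """Watson-Crick plus G-U wobble pairing, all allowed pairs at cost 0."""
    inf = math.inf
    cost = {(b1, b2): inf for b1 in BASES for b2 in BASES}
    for b1, b2 in ("AU", "UA", "CG", "GC", "GU", "UG"):
        cost[(b1, b2)] = 0.0
    return PairingMatrix(cost)


def _parse_gap(text: str, i: int, gap_cap: int) -> tuple[int, int]:
    """Parse ``[digits]`` starting at the ``[`` in column *i* (0-based).

    Returns (max_len, index one past the closing bracket).
    """
    j = text.find("]", i)
    if j == -1:
        raise QueryError(f"unclosed gap bracket at column {i + 1}")
    digits = text[i + 1 : j]
    if not digits or not digits.isdigit():
        raise QueryError(
            f"gap bound must be a non-negative integer in the gap at column {i + 1}"
        )
    bound = int(digits)
    if bound > gap_cap:
        raise QueryError(
            f"gap bound {bound} at column {i + 1} exceeds the cap of {gap_cap}"
        )
    return bound, j + 1


def parse_sequence_pattern(
    text: str, gap_cap: int = DEFAULT_GAP_CAP
) -> list[SeqElement]:
    """Parse a sequence pattern of IUPAC codes and ``[x]`` variable gaps.

    Lowercase is accepted and T is normalized to U.

    >>> parse_sequence_pattern("AN[3]G")
    [SeqElement(kind='code', code='A', max_len=0), ...]
    """
    if not text:
        raise QueryError("empty sequence pattern")
    out: list[SeqElement] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            bound, i = _parse_gap(text, i, gap_cap)
            out.append(SeqElement("gap", max_len=bound))
            continue
        c = ch.upper().replace("T", "U")
        if c not in IUPAC_EXPANSION:
            raise QueryError(
                f"invalid sequence pattern character {ch!r} at column {i + 1}"
            )
        out.append(SeqElement("code", code=c))
        i += 1
    return out


def parse_structure_pattern(
    text: str, gap_cap: int = DEFAULT_GAP_CAP
) -> list[StructElement]:
    """Parse a dot-bracket structure pattern with ``[x]`` variable gaps.

    Brackets must be balanced and properly nested (single bracket type,
    no pseudoknots).
    """
    if not text:
        raise QueryError("empty structure pattern")
    out: list[StructElement] = []
    depth = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            bound, i = _parse_gap(text, i, gap_cap)
            out.append(StructElement("gap", max_len=bound))
            continue
        if ch == ".":
            out.append(StructElement("dot"))
        elif ch == "(":
            out.append(StructElement("open"))
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise QueryError(
                    f"unbalanced ')' at column {i + 1} of structure pattern"
                )
            out.append(StructElement("close"))
        else:
            raise QueryError(
                f"invalid structure pattern character {ch!r} at column {i + 1}"
            )
        i += 1
    if depth != 0:
        raise QueryError("unbalanced brackets in structure pattern")
    return out


def make_query(
    seq: Iterable[SeqElement], struct: Iterable[StructElement]
) -> Query:
    """Combine parsed sequence and structure patterns into a validated Query.

    The two patterns must have equal length, with gaps at identical
    positions and identical bounds.  Bracket pairs are matched with a stack.
    """
    seq = tuple(seq)
    struct = tuple(struct)
    if len(seq) != len(struct):
        raise QueryError(
            f"sequence pattern has {len(seq)} elements but structure "
            f"pattern has {len(struct)}"
        )
    gap_slots: list[int] = []
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, (se, te) in enumerate(zip(seq, struct)):
        if (se.kind == "gap") != (te.kind == "gap"):
            raise QueryError(
                f"gap at element {i + 1} present in only one of the patterns"
            )
        if se.kind == "gap":
            if se.max_len != te.max_len:
                raise QueryError(
                    f"gap bound mismatch at element {i + 1}: "
                    f"[{se.max_len}] vs [{te.max_len}]"
                )
            gap_slots.append(i)
        elif te.kind == "open":
            stack.append(i)
        elif te.kind == "close":
            pairs.append((stack.pop(), i))
    pairs.sort()
    return Query(seq=seq, struct=struct, pairs=tuple(pairs), gap_slots=tuple(gap_slots))


def parse_query(
    seq_text: str, struct_text: str, gap_cap: int = DEFAULT_GAP_CAP
) -> Query:
    """Convenience wrapper: parse both pattern strings and combine them."""
    return make_query(
        parse_sequence_pattern(seq_text, gap_cap),
        parse_structure_pattern(struct_text, gap_cap),
    )


def render_sequence_pattern(elements: Iterable[SeqElement]) -> str:
    """Inverse of :func:`parse_sequence_pattern` on canonical text."""
    return "".join(
        f"[{e.max_len}]" if e.kind == "gap" else e.code for e in elements
    )


def render_structure_pattern(elements: Iterable[StructElement]) -> str:
    sym = {"dot": ".", "open": "(", "close": ")"}
    return "".join(
        f"[{e.max_len}]" if e.kind == "gap" else sym[e.kind] for e in elements
    )


def parse_pairing_matrix(text: str) -> PairingMatrix:
    """Parse a whitespace-delimited 4x4 cost matrix.

    Expected layout: a header row ``A C G U``, then four rows each starting
    with its base label followed by four entries (non-negative floats or
    ``inf``).  The row label gives the 5' base, the column label the 3' base.
    """
    rows = [line.split() for line in text.splitlines() if line.strip()]
    if not rows:
        raise QueryError("empty pairing matrix")
    header = [tok.upper() for tok in rows[0]]
    if header != list(BASES):
        raise QueryError(f"matrix header must be 'A C G U', got {' '.join(rows[0])!r}")
    if len(rows) != 5:
        raise QueryError(f"matrix must have 4 labelled rows, got {len(rows) - 1}")
    cost: dict[tuple[str, str], float] = {}
    seen: set[str] = set()
    for row in rows[1:]:
        if len(row) != 5:
            raise QueryError(f"matrix row must have a label and 4 entries: {row!r}")
        label = row[0].upper()
        if label not in BASES:
            raise QueryError(f"unknown matrix row label {row[0]!r}")
        if label in seen:
            raise QueryError(f"duplicate matrix row label {row[0]!r}")
        seen.add(label)
        for col, tok in zip(BASES, row[1:]):
            try:
                value = math.inf if tok.lower() in ("inf", "+inf") else float(tok)
            except ValueError:
                raise QueryError(f"invalid matrix entry {tok!r}") from None
            if value < 0 or math.isnan(value):
                raise QueryError(f"invalid matrix entry {tok!r}")
            cost[(label, col)] = value
    return PairingMatrix(cost)


def iupac_matches(code: str, base: str) -> bool:
    """Does a concrete target character satisfy a query IUPAC code?

    True iff ``base`` is one of A/C/G/U and lies in the expansion of
    ``code``.  Wildcards in the *target* (anything outside A/C/G/U after
    normalization) match no query code, including query ``N``.
    """
    try:
        return base in IUPAC_EXPANSION[code]
    except KeyError:
        raise QueryError(f"invalid IUPAC code {code!r}") from None


def pair_cost(matrix: PairingMatrix, b1: str, b2: str) -> float:
    """Cost of pairing two concrete target bases; ``inf`` rejects the pair.

    Non-ACGU target characters cannot pair at all.
    """
    return matrix.cost.get((b1, b2), math.inf)
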