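"""Synthetic targets with planted motif instances, and randomized instances
for stress testing.

:func:`generate_fixture` writes a random background sequence at a chosen GC
fraction and plants a known number of non-overlapping query instances at
random positions, recording the ground truth (position, realized gap
lengths, planted subsequence) so that search recall can be measured
exactly.  Planted instances are valid matches by construction: fixed codes
are instantiated from their IUPAC expansions, paired positions are drawn
from the matrix's allowed pairs and written consistently at both ends, and
gap-filled positions keep the background bases.

The ``random_*`` helpers produce randomized queries, targets and pairing
matrices within bounded complexity, used to drive engine-versus-oracle
equivalence testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TargetRecord
from .query import (
    IUPAC_EXPANSION,
    PairingMatrix,
    Query,
    default_pairing_matrix,
    make_query,
    parse_sequence_pattern,
    parse_structure_pattern,
)
from .results import element_layout

__all__ = [
    "PlantedInstance",
    "generate_fixture",
    "random_query",
    "random_target",
    "random_matrix",
    "GUANINE_APTAMER_EXAMPLE",
]


def _example_query() -> tuple[str, str]:
    """Two-hairpin, gapped, purine-riboswitch-aptamer-style descriptor.

    Built programmatically so the two pattern lines stay consistent:
    a 5-bp stem with a conserved 9-nt loop, a bounded gap, a second 5-bp
    stem with a conserved 7-nt loop, another bounded gap and a conserved
    junction tail.
    """
    seq = (
        "NNNNN" + "CUGUAUAAU" + "NNNNN"   # hairpin 1, conserved loop
        + "[3]"
        + "NNNNN" + "GGCAGUA" + "NNNNN"   # hairpin 2, conserved loop
        + "[3]"
        + "UCUACC"                         # conserved junction tail
    )
    struct = (
        "(((((" + "." * 9 + ")))))"
        + "[3]"
        + "(((((" + "." * 7 + ")))))"
        + "[3]"
        + "......"
    )
    return seq, struct


#: A guanine-riboswitch-aptamer-style example query: two gapped hairpins
#: with partially conserved loops joined by conserved junction nucleotides.
GUANINE_APTAMER_EXAMPLE = _example_query()


@dataclass(frozen=True)
class PlantedInstance:
    """Ground truth for one planted motif occurrence (start is 1-based)."""

    target_id: str
    start: int
    gap_lengths: tuple[int, ...]
    subsequence: str


def generate_fixture(
    q: Query,
    matrix: PairingMatrix | None = None,
    n_plants: int = 10,
    length: int = 10_000,
    gc: float = 0.5,
    seed: int = 0,
    target_id: str = "synthetic",
) -> tuple[TargetRecord, list[PlantedInstance]]:
    """A synthetic target with ``n_plants`` non-overlapping planted matches.

    The background is i.i.d. with P(G)=P(C)=gc/2 and P(A)=P(U)=(1-gc)/2.
    Fully reproducible from ``seed``.
    """
    matrix = matrix or default_pairing_matrix()
    if n_plants * q.max_span > length / 2:
        raise ValueError(
            f"cannot pack {n_plants} instances of max span {q.max_span} "
            f"into a length-{length} target"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(bases, size=length, p=probs)

    # realized gap vectors first, so each instance's span is known
    gap_vecs = [
        tuple(int(rng.integers(0, q.seq[s].max_len + 1)) for s in q.gap_slots)
        for _ in range(n_plants)
    ]
    placed: list[tuple[int, int]] = []  # (start, span), kept sorted
    for gv in gap_vecs:
        span = q.fixed_len + sum(gv)
        for attempt in range(100_000):
            start = int(rng.integers(0, length - span + 1))
            if all(start + span <= s or s + sp <= start for s, sp in placed):
                placed.append((start, span))
                break
        else:
            raise ValueError("could not place planted instances without overlap")

    truth: list[PlantedInstance] = []
    for (start, span), gv in zip(placed, gap_vecs):
        layout = element_layout(q, gv)
        for e, (off, _l) in zip(q.seq, layout):
            if e.kind == "code":
                choices = sorted(IUPAC_EXPANSION[e.code])
                seq[start + off] = choices[int(rng.integers(0, len(choices)))]
        for i, j in q.pairs:
            # a pair draw must also satisfy both positions' sequence codes,
            # otherwise the planted instance would not match its own query
            candidates = sorted(
                (b1, b2)
                for b1, b2 in matrix.allowed_pairs
                if b1 in IUPAC_EXPANSION[q.seq[i].code]
                and b2 in IUPAC_EXPANSION[q.seq[j].code]
            )
            if not candidates:
                raise ValueError(
                    f"no allowed pair satisfies the codes at elements {i},{j}"
                )
            b1, b2 = candidates[int(rng.integers(0, len(candidates)))]
            seq[start + layout[i][0]] = b1
            seq[start + layout[j][0]] = b2
        truth.append(
            PlantedInstance(
                target_id=target_id,
                start=start + 1,
                gap_lengths=gv,
                subsequence="".join(seq[start : start + span]),
            )
        )
    truth.sort(key=lambda t: t.start)
    return TargetRecord(id=target_id, seq="".join(seq)), truth


# ---------------------------------------------------------------------------
# randomized instances for equivalence testing
# ---------------------------------------------------------------------------


def random_target(rng: np.random.Generator, length: int, wildcard_p: float = 0.02) -> str:
    """Random ACGU sequence with occasional N wildcards."""
    alphabet = np.array(list("ACGUN"))
    p = np.array([1, 1, 1, 1, 0]) * (1 - wildcard_p) / 4
    p[4] = wildcard_p
    return "".join(rng.choice(alphabet, size=length, p=p))


def random_query(
    rng: np.random.Generator,
    max_hairpins: int = 3,
    max_gap_slots: int = 3,
    max_gap_bound: int = 3,
    ambiguity_p: float = 0.25,
) -> Query:
    """A random well-formed query of bounded complexity.

    Hairpins (stem 1-3 bp, loop 0-4 nt) separated and flanked by short
    unpaired linkers; a bounded number of variable gaps dropped into
    unpaired positions; codes drawn mostly concrete with some ambiguity.
    """
    codes = list("ACGU")
    ambig = sorted(c for c in IUPAC_EXPANSION if len(IUPAC_EXPANSION[c]) > 1)

    def draw_code() -> str:
        if rng.random() < ambiguity_p:
            return ambig[int(rng.integers(0, len(ambig)))]
        return codes[int(rng.integers(0, 4))]

    n_hp = int(rng.integers(0, max_hairpins + 1))
    seq_parts: list[str] = []
    struct_parts: list[str] = []
    gap_budget = int(rng.integers(0, max_gap_slots + 1))

    def unpaired_run(lo: int, hi: int, gap_p: float) -> None:
        nonlocal gap_budget
        for _ in range(int(rng.integers(lo, hi + 1))):
            if gap_budget and rng.random() < gap_p:
                bound = int(rng.integers(1, max_gap_bound + 1))
                seq_parts.append(f"[{bound}]")
                struct_parts.append(f"[{bound}]")
                gap_budget -= 1
            else:
                seq_parts.append(draw_code())
                struct_parts.append(".")

    unpaired_run(0, 3, 0.35)
    for _ in range(n_hp):
        stem = int(rng.integers(1, 4))
        seq_parts.append("".join(draw_code() for _ in range(stem)))
        struct_parts.append("(" * stem)
        unpaired_run(0, 4, 0.25)  # the loop
        seq_parts.append("".join(draw_code() for _ in range(stem)))
        struct_parts.append(")" * stem)
        unpaired_run(0, 3, 0.35)
    if not seq_parts:
        unpaired_run(1, 4, 0.35)
    if not seq_parts:
        seq_parts.append(draw_code())
        struct_parts.append(".")
    return make_query(
        parse_sequence_pattern("".join(seq_parts)),
        parse_structure_pattern("".join(struct_parts)),
    )


def random_matrix(rng: np.random.Generator, allow_p: float = 0.5) -> PairingMatrix:
    """A random cost matrix: each cell allowed with probability ``allow_p``
    at a small non-negative cost; the G-C pair is forced on when the draw
    allows nothing, since an all-infinite matrix is rejected at
    construction."""
    bases = "ACGU"
    cost = {}
    for b1 in bases:
        for b2 in bases:
            if rng.random() < allow_p:
                cost[(b1, b2)] = float(np.round(rng.uniform(0, 2), 1))
            else:
                cost[(b1, b2)] = float("inf")
    if all(v == float("inf") for v in cost.values()):
        cost[("G", "C")] = 0.0
    return PairingMatrix(cost)
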