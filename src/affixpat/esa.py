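"""Enhanced suffix arrays over nucleotide texts.

An enhanced suffix array is the lexicographically sorted array of suffix
start positions plus two auxiliary tables: the LCP array (longest common
prefix of each suffix with its lexicographic predecessor) and a child table
over the lcp-interval tree.  Together they support top-down traversal
equivalent to walking a suffix tree: from an interval of suffixes sharing a
common prefix, :func:`EnhancedSuffixArray.interval_extend` finds the
sub-interval whose suffixes continue with a given character, in time
proportional to the alphabet size.

Texts are normalized to the 6-symbol alphabet

    sentinel < A < C < G < U < wildcard

where the sentinel terminates the text and every non-ACGU input character
(N and friends) collapses to the single wildcard symbol: all wildcards are
equivalent at match time because a target wildcard satisfies no query code.
Wildcards take part in the index as an ordinary symbol; rejecting them is
the matcher's job, never the index's.

Suffix sorting uses prefix doubling on numpy ``lexsort`` (O(n log n)); the
LCP array is built with Kasai's algorithm and the child table with the
classic stack sweep over the LCP array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SENTINEL",
    "WILDCARD",
    "ALPHABET",
    "Interval",
    "EnhancedSuffixArray",
    "normalize_seq",
    "encode",
    "decode",
    "build_suffix_array",
    "build_lcp",
    "build_child_table",
]

# integer codes; sentinel sorts below everything
SENTINEL = 0
CODE_OF = {"A": 1, "C": 2, "G": 3, "U": 4, "#": 5}
CHAR_OF = {v: k for k, v in CODE_OF.items()} | {SENTINEL: "$"}
WILDCARD = CODE_OF["#"]
ALPHABET = (1, 2, 3, 4, 5)

_TRANS = str.maketrans(
    {chr(i): ("U" if chr(i) in "Tt"
              else chr(i).upper() if chr(i).upper() in "ACGU" else "#")
     for i in range(256)}
)


def normalize_seq(seq: str) -> str:
    """Uppercase, T->U, and collapse every non-ACGU character to ``#``."""
    return seq.translate(_TRANS)


def encode(seq: str) -> np.ndarray:
    """Normalized sequence -> uint8 code array (no sentinel appended)."""
    table = np.zeros(128, dtype=np.uint8)
    for ch, code in CODE_OF.items():
        table[ord(ch)] = code
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = table[raw]
    if np.any((codes == 0) & (raw != 0)):
        raise ValueError("sequence not normalized; call normalize_seq first")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(CHAR_OF[int(c)] for c in codes)


@dataclass(frozen=True)
class Interval:
    """Rows ``lo..hi`` (inclusive) of the suffix array, all sharing a
    common prefix of length ``depth`` (the matched word)."""

    lo: int
    hi: int
    depth: int

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1


def build_suffix_array(codes: np.ndarray) -> np.ndarray:
    """Sorted suffix start positions of a code array ending in the sentinel.

    Prefix doubling: ranks are refined by lexsorting (rank[i], rank[i+k])
    pairs until all ranks are distinct, which the unique sentinel guarantees.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    n = len(codes)
    if n == 0:
        raise ValueError("empty text")
    if codes[-1] != SENTINEL or np.any(codes[:-1] == SENTINEL):
        raise ValueError("text must end with a single terminal sentinel")
    if codes.max(initial=0) > max(ALPHABET):
        raise ValueError("character outside the normalized alphabet")
    rank = codes.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        labels = np.empty(n, dtype=np.int64)
        labels[0] = 0
        labels[1:] = np.cumsum((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1]))
        rank = np.empty(n, dtype=np.int64)
        rank[order] = labels
        if labels[-1] == n - 1:
            return order.astype(np.int64)
        k *= 2


def build_lcp(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] compares suffixes sa[i-1] and sa[i], lcp[0]=0."""
    n = len(sa)
    text = bytes(np.asarray(codes, dtype=np.uint8))  # bytes indexing is fast
    rank = np.empty(n, dtype=np.int64)
    rank[np.asarray(sa)] = np.arange(n)
    rank_l = rank.tolist()
    sa_l = np.asarray(sa).tolist()
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = rank_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return np.asarray(lcp, dtype=np.int64)


def build_child_table(lcp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Child table of the lcp-interval tree as (up, down, next_l) arrays.

    ``up`` has one extra slot: ``up[i]`` refers to the boundary between rows
    i-1 and i, so ``up[n]`` is defined (used when querying intervals ending
    at the last row).  -1 marks an undefined entry.
    """
    n = len(lcp)
    up = np.full(n + 1, -1, dtype=np.int64)
    down = np.full(n, -1, dtype=np.int64)
    next_l = np.full(n, -1, dtype=np.int64)
    lcp_l = np.asarray(lcp).tolist()

    # up / down sweep; a virtual lcp of -1 at position n flushes the stack
    stack = [0]
    last = -1
    for i in range(1, n + 1):
        v = lcp_l[i] if i < n else -1
        while stack and v < lcp_l[stack[-1]]:
            last = stack.pop()
            if stack and v <= lcp_l[stack[-1]] and lcp_l[stack[-1]] != lcp_l[last]:
                down[stack[-1]] = last
        if last != -1:
            up[i] = last
            last = -1
        if i < n:
            stack.append(i)

    # next-l-index sweep
    stack = [0]
    for i in range(1, n):
        while lcp_l[i] < lcp_l[stack[-1]]:
            stack.pop()
        if lcp_l[i] == lcp_l[stack[-1]]:
            next_l[stack.pop()] = i
        stack.append(i)
    return up, down, next_l


class EnhancedSuffixArray:
    """Suffix array + LCP array + child table for one normalized sequence.

    Attributes
    ----------
    text : str
        Normalized sequence including the terminal ``$`` sentinel.
    codes, sa, lcp : numpy arrays as documented in the builders.
    """

    def __init__(self, seq: str):
        self.text = normalize_seq(seq) + "$"
        self.codes = np.append(encode(self.text[:-1]), np.uint8(SENTINEL))
        self.sa = build_suffix_array(self.codes)
        self.lcp = build_lcp(self.codes, self.sa)
        self.up, self.down, self.next_l = build_child_table(self.lcp)
        self.n = len(self.codes)

    @classmethod
    def from_arrays(
        cls, text: str, sa: np.ndarray, lcp: np.ndarray
    ) -> "EnhancedSuffixArray":
        """Rebuild from persisted arrays (child table is recomputed)."""
        obj = cls.__new__(cls)
        obj.text = text
        obj.codes = np.append(encode(text[:-1]), np.uint8(SENTINEL))
        obj.sa = np.asarray(sa, dtype=np.int64)
        obj.lcp = np.asarray(lcp, dtype=np.int64)
        obj.up, obj.down, obj.next_l = build_child_table(obj.lcp)
        obj.n = len(obj.codes)
        return obj

    def full_interval(self) -> Interval:
        return Interval(0, self.n - 1, 0)

    def _interval_lcp(self, lo: int, hi: int) -> int:
        """The lcp value of the (non-singleton) lcp-interval containing
        exactly rows lo..hi, or of its enclosing interval when lo..hi is a
        plain depth-d slice; callers only use it when lo < hi."""
        u = self.up[hi + 1]
        if lo < u <= hi:
            return int(self.lcp[u])
        return int(self.lcp[self.down[lo]])

    def _child_boundaries(self, lo: int, hi: int, ell: int) -> list[int]:
        """l-indices splitting interval [lo, hi] of value ell into children."""
        if lo == 0 and hi == self.n - 1:
            first = self.next_l[0] if self.next_l[0] != -1 else -1
            if first == -1:
                return []
            bounds = [int(first)]
        else:
            u = self.up[hi + 1]
            first = int(u) if lo < u <= hi else int(self.down[lo])
            bounds = [first]
        while True:
            nxt = self.next_l[bounds[-1]]
            if nxt == -1 or nxt > hi:
                break
            bounds.append(int(nxt))
        return bounds

    def interval_extend(self, iv: Interval, c: int) -> Interval | None:
        """Maximal sub-interval whose suffixes read character ``c`` at
        position ``iv.depth``; None when no suffix does."""
        lo, hi, d = iv.lo, iv.hi, iv.depth
        codes, sa = self.codes, self.sa
        if lo == hi:
            pos = int(sa[lo]) + d
            if pos < self.n and codes[pos] == c:
                return Interval(lo, hi, d + 1)
            return None
        if lo == 0 and hi == self.n - 1 and d == 0:
            ell = 0
        else:
            ell = self._interval_lcp(lo, hi)
        if d < ell:
            # all suffixes already share the character at this depth
            if codes[int(sa[lo]) + d] == c:
                return Interval(lo, hi, d + 1)
            return None
        # d == ell: descend to the child interval starting with c
        bounds = self._child_boundaries(lo, hi, ell)
        starts = [lo] + bounds
        ends = [b - 1 for b in bounds] + [hi]
        for a, b in zip(starts, ends):
            ch = int(codes[int(sa[a]) + d]) if int(sa[a]) + d < self.n else -1
            if ch == c:
                return Interval(a, b, d + 1)
            if ch > c:
                break
        return None

    def find(self, word: np.ndarray | list[int]) -> Interval | None:
        """Interval of a whole word, by chained extension from the root."""
        iv = self.full_interval()
        for c in word:
            iv = self.interval_extend(iv, int(c))
            if iv is None:
                return None
        return iv

    def word_of(self, iv: Interval) -> np.ndarray:
        """The matched word represented by an interval."""
        start = int(self.sa[iv.lo])
        return self.codes[start : start + iv.depth]

    def occurrences(self, iv: Interval) -> np.ndarray:
        """Start positions (0-based) of the interval's word in the text."""
        return np.sort(np.asarray(self.sa[iv.lo : iv.hi + 1]))
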