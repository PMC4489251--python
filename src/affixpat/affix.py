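"""Affix arrays: paired forward/reverse enhanced suffix arrays with lazy links.

The forward array indexes the target; the reverse-prefix array is the
enhanced suffix array of the reversed target.  An interval representing a
word w in one array corresponds to the interval representing reverse(w) in
the other — both cover exactly the same set of occurrences in the target.
That correspondence (the affix link) is what lets a search extend a match
leftwards as well as rightwards: rightward extension walks the forward
array, leftward extension walks the reverse array, and the link translates
the current interval whenever the active direction flips.

Building all links up front would dominate construction time, so links are
computed only when the search first needs one — by descending the opposite
array with the reversed word — and cached for the lifetime of the object.

The whole structure (minus the lazy link cache) can be saved to a cache
file and reloaded for later queries against the same target; the file
carries a digest of the normalized text so a stale cache is detected.
"""

from __future__ import annotations

import hashlib
import struct
from typing import Literal

import numpy as np

from .esa import EnhancedSuffixArray, Interval, normalize_seq

__all__ = [
    "AffixArray",
    "build_affix_array",
    "save_index",
    "load_index",
    "IndexFileError",
]

MAGIC = b"AFXIDX"
FORMAT_VERSION = 1

FWD = "fwd"
REV = "rev"
Direction = Literal["fwd", "rev"]


class IndexFileError(IOError):
    """A cache file is unreadable: wrong magic/version, stale digest or
    truncated payload."""


def _digest(normalized: str) -> bytes:
    return hashlib.sha256(normalized.encode("ascii")).digest()


class AffixArray:
    """Forward + reverse enhanced suffix arrays over one target record."""

    def __init__(self, fwd: EnhancedSuffixArray, rev: EnhancedSuffixArray):
        self.fwd = fwd
        self.rev = rev
        self.n = fwd.n - 1  # text length without sentinel
        self._links: dict[tuple[str, int, int, int], Interval] = {}
        # unbounded by default; set to an int to bound the lazy link cache
        self.link_cache_limit: int | None = None

    def esa(self, direction: Direction) -> EnhancedSuffixArray:
        return self.fwd if direction == FWD else self.rev

    @property
    def link_cache_size(self) -> int:
        return len(self._links)

    def affix_link(self, direction: Direction, iv: Interval) -> Interval:
        """Interval in the opposite array representing the reversed word.

        ``direction`` names the array ``iv`` lives in.  Computed on first
        use by walking the opposite array with the reversed word, then
        cached; an interval always has a link (same occurrence set).
        """
        key = (direction, iv.lo, iv.hi, iv.depth)
        cached = self._links.get(key)
        if cached is not None:
            return cached
        src = self.esa(direction)
        dst = self.esa(REV if direction == FWD else FWD)
        word = src.word_of(iv)
        linked = dst.find(word[::-1])
        if linked is None:  # pragma: no cover - violated only by corruption
            raise RuntimeError("affix link not found; index is inconsistent")
        if self.link_cache_limit is None or len(self._links) < self.link_cache_limit:
            self._links[key] = linked
        return linked

    def positions(self, direction: Direction, iv: Interval) -> np.ndarray:
        """Start positions of the interval's word in the *forward* text."""
        occ = self.esa(direction).occurrences(iv)
        if direction == FWD:
            return occ
        return np.sort(self.n - occ - iv.depth)


def build_affix_array(seq: str) -> AffixArray:
    """Index one target sequence (raw or normalized) in both directions."""
    if not seq:
        raise ValueError("empty target record")
    normalized = normalize_seq(seq)
    return AffixArray(
        EnhancedSuffixArray(normalized), EnhancedSuffixArray(normalized[::-1])
    )


def _pack_array(arr: np.ndarray) -> bytes:
    data = np.asarray(arr, dtype="<i8").tobytes()
    return struct.pack("<Q", len(data)) + data


def save_index(afx: AffixArray, path) -> None:
    """Persist magic, version, text digest and the two arrays' sa/lcp.

    The lazy link cache is deliberately not persisted; child tables are
    cheap to rebuild and are recomputed on load.
    """
    normalized = afx.fwd.text[:-1]
    blob = bytearray()
    blob += MAGIC
    blob += struct.pack("<I", FORMAT_VERSION)
    blob += _digest(normalized)
    blob += struct.pack("<Q", len(normalized))
    for esa in (afx.fwd, afx.rev):
        blob += _pack_array(esa.sa)
        blob += _pack_array(esa.lcp)
    with open(path, "wb") as fh:
        fh.write(bytes(blob))


def load_index(path, seq: str) -> AffixArray:
    """Load a cache file and verify it matches the supplied target sequence."""
    with open(path, "rb") as fh:
        blob = fh.read()
    off = 0

    def take(k: int) -> bytes:
        nonlocal off
        if off + k > len(blob):
            raise IndexFileError(f"truncated index file {path}")
        out = blob[off : off + k]
        off += k
        return out

    if take(len(MAGIC)) != MAGIC:
        raise IndexFileError(f"{path} is not an affix index file")
    (version,) = struct.unpack("<I", take(4))
    if version != FORMAT_VERSION:
        raise IndexFileError(
            f"index format version {version} != supported {FORMAT_VERSION}"
        )
    digest = take(32)
    normalized = normalize_seq(seq)
    if digest != _digest(normalized):
        raise IndexFileError(
            f"index digest mismatch: {path} was built from a different sequence"
        )
    (n,) = struct.unpack("<Q", take(8))
    if n != len(normalized):  # digest already guards this; belt and braces
        raise IndexFileError("index length mismatch")

    def take_array() -> np.ndarray:
        (nbytes,) = struct.unpack("<Q", take(8))
        return np.frombuffer(take(nbytes), dtype="<i8").astype(np.int64)

    texts = (normalized + "$", normalized[::-1] + "$")
    esas = []
    for text in texts:
        sa = take_array()
        lcp = take_array()
        if len(sa) != n + 1 or len(lcp) != n + 1:
            raise IndexFileError(f"truncated index file {path}")
        esas.append(EnhancedSuffixArray.from_arrays(text, sa, lcp))
    if off != len(blob):
        raise IndexFileError(f"trailing bytes in index file {path}")
    return AffixArray(*esas)
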