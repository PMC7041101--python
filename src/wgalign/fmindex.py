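"""BWT/FM-index over a reference genome and its reverse complement.

The indexed text is ``R · sep · revcomp(R) · $`` where ``R`` is the
concatenation of all reference records joined by separator symbols.
Separators never match a search symbol, so no exact match can span a record
junction or the forward/reverse boundary; the final terminator is the unique
smallest symbol, which makes the suffix order a rotation order and the LF
mapping exact.  Backward search over the BWT
answers exact-substring queries in O(|pattern|) rank operations; because the
reverse complement is part of the text, a single search covers both strands.

The suffix array is kept unsampled and the occurrence (rank) table is stored
cumulatively at every position, trading memory for simplicity: ``locate`` and
``extend_one`` are O(1) array lookups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genome import (
    Genome,
    InvalidSequenceError,
    SEP_CODE,
    TERM_CODE,
    encode,
    revcomp_codes,
)

_MAGIC = "wgalign-fmindex"
_VERSION = 1

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class SARange:
    """An inclusive interval [lo, hi] of suffix-array rows.

    The width ``hi - lo + 1`` is the number of occurrences of the pattern the
    range represents.  The canonical empty range has ``hi < lo`` and is
    absorbing under extension.
    """

    lo: int
    hi: int

    @property
    def width(self) -> int:
        return max(0, self.hi - self.lo + 1)

    @property
    def is_empty(self) -> bool:
        return self.hi < self.lo


EMPTY_RANGE = SARange(0, -1)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers, numpy lexsorts).

    Shorter suffixes sort before any longer suffix sharing their prefix (the
    out-of-range rank is -1, below every real rank), which matches a
    terminator-at-the-end convention.
    """
    n = len(codes)
    rank = codes.astype(np.int32)
    order = np.argsort(rank, kind="stable").astype(np.int32)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int32)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank)).astype(np.int32)
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=np.int32)
        changed[0] = 0
        changed[1:] = ((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])).astype(np.int32)
        new_rank = np.empty(n, dtype=np.int32)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


class ReferenceIndex:
    """FM-index over one or more reference records plus reverse complement."""

    def __init__(
        self,
        text: np.ndarray,
        sa: np.ndarray,
        bwt: np.ndarray,
        counts: np.ndarray,
        occ: np.ndarray,
        names: list[str],
        lengths: np.ndarray,
        offsets: np.ndarray,
    ) -> None:
        self.text = text
        self.sa = sa
        self.bwt = bwt
        self.counts = counts  # counts[c] = number of symbols < c in text
        self.occ = occ  # occ[c-1, i] = occurrences of code c in bwt[:i]
        self.names = names
        self.lengths = lengths
        self.offsets = offsets  # 0-based start of each record within R
        self.len_r = int(offsets[-1] + lengths[-1]) if len(lengths) else 0
        self.boundary = self.len_r  # text[boundary] is the mid separator

    # ------------------------------------------------------------------ build

    @classmethod
    def build(cls, reference: Genome | list[Genome]) -> "ReferenceIndex":
        genomes = [reference] if isinstance(reference, Genome) else list(reference)
        if not genomes:
            raise InvalidSequenceError("no reference records given")
        for g in genomes:
            g.validate()

        names = [g.name for g in genomes]
        lengths = np.array([len(g) for g in genomes], dtype=np.int64)
        offsets = np.zeros(len(genomes), dtype=np.int64)
        for i in range(1, len(genomes)):
            offsets[i] = offsets[i - 1] + lengths[i - 1] + 1  # +1 for separator

        parts = []
        for i, g in enumerate(genomes):
            if i:
                parts.append(np.array([SEP_CODE], dtype=np.uint8))
            parts.append(encode(g.seq))
        r_codes = np.concatenate(parts)
        sep = np.array([SEP_CODE], dtype=np.uint8)
        term = np.array([TERM_CODE], dtype=np.uint8)
        text = np.concatenate([r_codes, sep, revcomp_codes(r_codes), term])

        sa = _suffix_array(text)
        n = len(text)
        bwt = text[(sa - 1) % n]

        bincount = np.bincount(text, minlength=8).astype(np.int64)
        counts = np.zeros(8, dtype=np.int64)
        counts[1:] = np.cumsum(bincount)[:-1]

        occ = np.zeros((4, n + 1), dtype=np.int32)
        for c in range(1, 5):
            occ[c - 1, 1:] = np.cumsum(bwt == c, dtype=np.int32)

        return cls(text, sa, bwt, counts, occ, names, lengths, offsets)

    # ----------------------------------------------------------------- search

    def full_range(self) -> SARange:
        return SARange(0, len(self.text) - 1)

    def extend_one(self, rng: SARange, symbol: int | str) -> SARange:
        """SA range of ``symbol . S`` given the range of pattern S."""
        if rng.is_empty:
            return EMPTY_RANGE
        if isinstance(symbol, str):
            symbol = int(encode(symbol)[0])
        if not 1 <= symbol <= 4:  # N or separator never matches
            return EMPTY_RANGE
        c = self.counts[symbol]
        lo = c + self.occ[symbol - 1, rng.lo]
        hi = c + self.occ[symbol - 1, rng.hi + 1] - 1
        if hi < lo:
            return EMPTY_RANGE
        return SARange(int(lo), int(hi))

    def backward_search(self, pattern: str) -> SARange:
        """SA range of all occurrences of ``pattern`` in the indexed text."""
        rng = self.full_range()
        for code in encode(pattern)[::-1]:
            rng = self.extend_one(rng, int(code))
            if rng.is_empty:
                return EMPTY_RANGE
        return rng

    def _record_at(self, r_pos: int) -> int:
        return int(np.searchsorted(self.offsets, r_pos, side="right") - 1)

    def locate(self, rng: SARange, length: int) -> list[tuple[int, int, str]]:
        """Map SA rows of a length-``length`` pattern to reference hits.

        Returns ``(record_index, position, strand)`` triples with 1-based
        in-record positions.  A hit in the forward half reports the pattern
        itself on the forward strand; a hit in the reverse-complement half is
        converted to the coordinate of the pattern's reverse complement in the
        record, reported as a reverse-strand hit.
        """
        if rng.is_empty:
            return []
        return self.locate_rows(rng.lo, rng.hi, length)

    def locate_rows(self, lo: int, hi: int, length: int) -> list[tuple[int, int, str]]:
        """As :meth:`locate`, for a raw inclusive row interval."""
        hits = []
        for row in range(lo, hi + 1):
            t = int(self.sa[row])
            if t + length <= self.len_r:
                rec = self._record_at(t)
                pos = t - int(self.offsets[rec]) + 1
                hits.append((rec, pos, FORWARD))
            else:
                tp = t - (self.len_r + 1)
                start_r = self.len_r - tp - length
                rec = self._record_at(start_r)
                pos = start_r - int(self.offsets[rec]) + 1
                hits.append((rec, pos, REVERSE))
        return hits

    # -------------------------------------------------------------- persistence

    def save(self, path) -> None:
        header = json.dumps(
            {
                "magic": _MAGIC,
                "version": _VERSION,
                "names": self.names,
            }
        )
        np.savez(
            path,
            header=np.frombuffer(header.encode("utf-8"), dtype=np.uint8),
            text=self.text,
            sa=self.sa,
            bwt=self.bwt,
            counts=self.counts,
            occ=self.occ,
            lengths=self.lengths,
            offsets=self.offsets,
        )

    @classmethod
    def load(cls, path) -> "ReferenceIndex":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode("utf-8"))
            if header.get("magic") != _MAGIC:
                raise ValueError(f"{path}: not a wgalign index file")
            if header.get("version") != _VERSION:
                raise ValueError(f"{path}: unsupported index version")
            return cls(
                text=data["text"],
                sa=data["sa"],
                bwt=data["bwt"],
                counts=data["counts"],
                occ=data["occ"],
                names=list(header["names"]),
                lengths=data["lengths"],
                offsets=data["offsets"],
            )


def build_index(reference: Genome | list[Genome]) -> ReferenceIndex:
    """Build the FM-index of a reference genome (see :class:`ReferenceIndex`)."""
    return ReferenceIndex.build(reference)
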