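"""LMEM seeding: scan a query against the FM-index and emit simple pairs.

A *local maximal exact match* (LMEM) is a common substring of reference and
query that begins at a given query position and extends until no occurrence
in the index can be extended further.  An LMEM of length >= ``k`` with fewer
than ``f`` occurrences is turned into one simple pair per occurrence.

Simple pairs on the reverse strand carry query coordinates in the
reverse-complemented query frame, so that within either strand a pair is a
plain co-linear match and ``PosDiff = i1 - j1`` is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .fmindex import FORWARD, REVERSE, ReferenceIndex
from .genome import Genome, encode_complement


@dataclass
class SeedParams:
    """Seeding and chaining thresholds.

    k: minimum LMEM length; f: maximum occurrence count (seeds with >= f
    occurrences are discarded as repetitive); sensitive restarts the scan a
    fixed ``stride`` past the previous start instead of after the LMEM.
    ``max_diff`` bounds the PosDiff spread inside one cluster (and hence the
    indel size between adjacent anchors); ``outlier_tol`` is the
    neighbour-PosDiff tolerance of the outlier filter; gaps longer than
    ``gap_break`` trigger a shared-k-mer similarity test with word size
    ``sim_kmer`` and break the region when fewer than gap/``kmer_divisor``
    k-mers are shared.
    """

    k: int = 30
    f: int = 5
    sensitive: bool = False
    stride: int = 5
    max_diff: int = 25
    outlier_tol: int = 5
    gap_break: int = 300
    kmer_divisor: int = 3
    sim_kmer: int = 8

    def __post_init__(self) -> None:
        for name in ("k", "f", "stride", "max_diff", "outlier_tol", "gap_break", "kmer_divisor", "sim_kmer"):
            if getattr(self, name) < 1:
                raise ValueError(f"SeedParams.{name} must be >= 1")


@dataclass
class SimplePair:
    """Identical fragments P[i1..i2] = Q[j1..j2] (1-based inclusive).

    For reverse-strand pairs the j coordinates refer to the
    reverse-complemented query.  ``pos_diff`` is i1 - j1 in that frame;
    ``unique`` records whether the originating LMEM had a single occurrence.
    """

    i1: int
    i2: int
    j1: int
    j2: int
    strand: str = FORWARD
    rec: int = 0
    unique: bool = True
    pos_diff: int = field(init=False)

    def __post_init__(self) -> None:
        if self.i2 - self.i1 != self.j2 - self.j1:
            raise ValueError("simple pair fragments must have equal length")
        self.pos_diff = self.i1 - self.j1

    @property
    def length(self) -> int:
        return self.i2 - self.i1 + 1


def partition_query(query_length: int, n_blocks: int) -> list[tuple[int, int]]:
    """Split [1, query_length] into ``n_blocks`` near-equal 1-based intervals.

    Blocks tile the query exactly; ``n_blocks`` is clamped to the query
    length.  Scanning treats a block's right edge as the last permitted LMEM
    start, while extension may run past it, so the seed set after
    deduplication does not depend on the block count.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n_blocks = min(n_blocks, query_length)
    bounds = np.linspace(0, query_length, n_blocks + 1, dtype=np.int64)
    return [(int(bounds[b]) + 1, int(bounds[b + 1])) for b in range(n_blocks)]


def find_lmems(
    index: ReferenceIndex,
    query: Genome,
    params: SeedParams,
    n_blocks: int = 1,
) -> list[SimplePair]:
    """Identify all LMEM seeds of ``query`` against the index.

    The query is scanned in ``n_blocks`` independent blocks (the
    multi-threading unit).  Each block records its full scan trajectory
    (every restart position); the merged result then follows the global
    trajectory exactly — when it enters a block out of phase it single-steps
    until it lands on a recorded restart position and adopts the rest of
    that block's result.  The seed set is therefore identical to a
    single-block scan for any block count.
    """
    qlen = len(query)
    if qlen == 0:
        return []
    comp_codes = encode_complement(query.seq)
    n_text = len(index.text)

    def scan(start0: int, end0: int):
        return _kernels.scan_lmems(
            comp_codes,
            index.counts,
            index.occ,
            n_text,
            params.k,
            params.f,
            params.sensitive,
            params.stride,
            start0,
            end0,
        )

    blocks = partition_query(qlen, n_blocks)
    block_data = [(start - 1, end - 1, *scan(start - 1, end - 1)) for start, end in blocks]

    raw: list[tuple[int, int, int, int]] = []  # (j1_0, j2_0, lo, hi)
    pos = 0
    bi = 0
    while pos < qlen:
        while bi < len(block_data) - 1 and pos > block_data[bi][1]:
            bi += 1
        _, bend, j1s, j2s, los, his, starts, final_j = block_data[bi]
        if pos > bend:
            break
        k = int(np.searchsorted(starts, pos))
        if k < len(starts) and starts[k] == pos:
            # on this block's trajectory: adopt its remaining seeds
            sel = int(np.searchsorted(j1s, pos))
            for t in range(sel, len(j1s)):
                raw.append((int(j1s[t]), int(j2s[t]), int(los[t]), int(his[t])))
            pos = int(final_j)
        else:
            # out of phase (a block boundary cut an LMEM): single scan step
            sj1, sj2, slo, shi, _, nxt = scan(pos, pos)
            for t in range(len(sj1)):
                raw.append((int(sj1[t]), int(sj2[t]), int(slo[t]), int(shi[t])))
            pos = int(nxt)

    pairs: list[SimplePair] = []
    for j1_0, j2_0, lo, hi in raw:
        length = j2_0 - j1_0 + 1
        width = hi - lo + 1
        # the searched pattern is revcomp(Q[j1..j2]); a hit of that pattern
        # on the reverse strand is a forward-frame match of the query
        # fragment, and vice versa
        for rec, ppos, strand in index.locate_rows(lo, hi, length):
            if strand == REVERSE:
                pairs.append(
                    SimplePair(
                        i1=ppos,
                        i2=ppos + length - 1,
                        j1=j1_0 + 1,
                        j2=j2_0 + 1,
                        strand=FORWARD,
                        rec=rec,
                        unique=width == 1,
                    )
                )
            else:
                jr1 = qlen - j2_0
                pairs.append(
                    SimplePair(
                        i1=ppos,
                        i2=ppos + length - 1,
                        j1=jr1,
                        j2=jr1 + length - 1,
                        strand=REVERSE,
                        rec=rec,
                        unique=width == 1,
                    )
                )

    pairs.sort(key=lambda s: (s.rec, s.strand, s.j1, s.i1))
    return pairs
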