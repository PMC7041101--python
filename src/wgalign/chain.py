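"""Chaining: cluster simple pairs by PosDiff into similar regions.

Co-linear seeds share a similar ``PosDiff`` (reference start minus query
start), so sorting all simple pairs by PosDiff and breaking wherever two
adjacent sorted values differ by more than ``max_diff`` partitions the seeds
into candidate regions.  Each cluster is then cleaned up in query order:

1. outlier seeds whose PosDiff disagrees with both neighbours are removed;
2. seeds occupying the same query interval (repeat copies) are reduced to
   the copy most consistent with the nearest unique seed;
3. long gaps (> ``gap_break``) with dissimilar flanking sequence split the
   cluster into separate regions;
4. overlapping adjacent seeds are trimmed (the preceding seed is shortened);
5. remaining gaps between adjacent seeds are filled with *normal pairs*,
   the units later closed by (un)gapped alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .fmindex import FORWARD
from .seeds import SeedParams, SimplePair

EMPTY = -1


@dataclass
class NormalPair:
    """Possibly empty-sided fragment pair between two adjacent simple pairs.

    A side equal to (-1, -1) denotes an empty fragment (a pure insertion or
    deletion).  ``ptype`` is assigned by the aligner: "I" equal-size
    substitution-only, "II" one side empty, "III" general gapped.
    """

    i1: int
    i2: int
    j1: int
    j2: int
    ptype: str | None = None

    @property
    def p_empty(self) -> bool:
        return self.i1 == EMPTY

    @property
    def q_empty(self) -> bool:
        return self.j1 == EMPTY

    @property
    def p_len(self) -> int:
        return 0 if self.p_empty else self.i2 - self.i1 + 1

    @property
    def q_len(self) -> int:
        return 0 if self.q_empty else self.j2 - self.j1 + 1


Pair = Union[SimplePair, NormalPair]


@dataclass
class SimilarRegion:
    """An ordered, co-linear mixture of simple and normal pairs.

    Pairs are sorted by query coordinate and contiguous on both sequences
    (empty-sided normal pairs are contiguous on their non-empty side); the
    region yields exactly one local alignment.
    """

    pairs: list[Pair]
    strand: str = FORWARD
    rec: int = 0
    p_start: int = field(init=False)
    p_end: int = field(init=False)
    q_start: int = field(init=False)
    q_end: int = field(init=False)

    def __post_init__(self) -> None:
        simples = [p for p in self.pairs if isinstance(p, SimplePair)]
        self.p_start = simples[0].i1
        self.p_end = simples[-1].i2
        self.q_start = simples[0].j1
        self.q_end = simples[-1].j2


def cluster_by_posdiff(
    pairs: list[SimplePair], params: SeedParams
) -> list[list[SimplePair]]:
    """Partition seeds into clusters of similar PosDiff.

    Seeds are sorted by PosDiff and a cluster breaks wherever two adjacent
    sorted values differ by more than ``max_diff``; every seed lands in
    exactly one cluster.
    """
    if not pairs:
        return []
    ordered = sorted(pairs, key=lambda s: (s.pos_diff, s.j1, s.i1))
    clusters: list[list[SimplePair]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        if abs(cur.pos_diff - prev.pos_diff) > params.max_diff:
            clusters.append([cur])
        else:
            clusters[-1].append(cur)
    return clusters


def sort_by_query(cluster: list[SimplePair]) -> list[SimplePair]:
    return sorted(cluster, key=lambda s: (s.j1, s.i1))


def remove_outliers(
    cluster: list[SimplePair], params: SeedParams
) -> list[SimplePair]:
    """Drop seeds that are not co-linear with their query-order neighbours.

    An interior seed is an outlier when its PosDiff differs by more than
    ``outlier_tol`` from both adjacent seeds; a terminal seed (which has a
    single neighbour) is an outlier when the difference exceeds ``max_diff``.
    All outliers are marked in one pass and removed together, preserving
    query order.
    """
    if len(cluster) <= 1:
        return list(cluster)
    ordered = sort_by_query(cluster)
    keep = []
    last = len(ordered) - 1
    for m, s in enumerate(ordered):
        if m == 0:
            drop = abs(s.pos_diff - ordered[1].pos_diff) > params.max_diff
        elif m == last:
            drop = abs(s.pos_diff - ordered[m - 1].pos_diff) > params.max_diff
        else:
            drop = (
                abs(s.pos_diff - ordered[m - 1].pos_diff) > params.outlier_tol
                and abs(s.pos_diff - ordered[m + 1].pos_diff) > params.outlier_tol
            )
        if not drop:
            keep.append(s)
    return keep


def resolve_duplicates(cluster: list[SimplePair]) -> list[SimplePair]:
    """Keep one seed per query interval when a fragment has repeat copies.

    Among seeds sharing the same (j1, j2), the survivor is the one whose
    PosDiff is closest to that of the nearest unique seed in query order
    (nearer side wins, left on ties); if the cluster has no unique seed the
    reference value is the cluster's median PosDiff.  Exact ties keep the
    first seed in sorted order, fixed for determinism.
    """
    ordered = sort_by_query(cluster)
    if not ordered:
        return []
    groups: dict[tuple[int, int], list[int]] = {}
    for idx, s in enumerate(ordered):
        groups.setdefault((s.j1, s.j2), []).append(idx)
    if all(len(g) == 1 for g in groups.values()):
        return ordered

    uniques = [idx for idx, s in enumerate(ordered) if s.unique]
    pds = sorted(s.pos_diff for s in ordered)
    median_pd = pds[(len(pds) - 1) // 2]

    def reference_posdiff(members: list[int]) -> int:
        if not uniques:
            return median_pd
        lo = members[0]
        hi = members[-1]
        left = [u for u in uniques if u < lo]
        right = [u for u in uniques if u > hi]
        cands = []
        if left:
            cands.append((ordered[lo].j1 - ordered[left[-1]].j1, ordered[left[-1]].pos_diff))
        if right:
            cands.append((ordered[right[0]].j1 - ordered[hi].j1, ordered[right[0]].pos_diff))
        cands.sort(key=lambda t: t[0])
        return cands[0][1]

    drop = set()
    for members in groups.values():
        if len(members) == 1:
            continue
        ref_pd = reference_posdiff(members)
        best = min(members, key=lambda idx: (abs(ordered[idx].pos_diff - ref_pd), idx))
        drop.update(m for m in members if m != best)
    return [s for idx, s in enumerate(ordered) if idx not in drop]


def _shared_kmers(a: str, b: str, k: int) -> int:
    if len(a) < k or len(b) < k:
        return 0
    kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    shared = set()
    for i in range(len(b) - k + 1):
        w = b[i : i + k]
        if w in kmers_a:
            shared.add(w)
    return len(shared)


def split_on_dissimilar_gaps(
    cluster: list[SimplePair],
    p_seq: str,
    q_seq: str,
    params: SeedParams,
) -> list[list[SimplePair]]:
    """Split a cluster at long gaps whose flanking fragments are dissimilar.

    For adjacent seeds a, b (query order) with gap(a, b) = j_b1 - j_a2 more
    than ``gap_break``, the gap fragments on both sequences are compared by
    counting distinct shared k-mers; fewer than gap / ``kmer_divisor`` shared
    k-mers makes b the start of a new region.  ``p_seq``/``q_seq`` are the
    full sequences the cluster coordinates refer to.
    """
    ordered = sort_by_query(cluster)
    if not ordered:
        return []
    parts: list[list[SimplePair]] = [[ordered[0]]]
    for a, b in zip(ordered, ordered[1:]):
        gap = b.j1 - a.j2
        if gap > params.gap_break:
            p_frag = p_seq[a.i2 : b.i1 - 1]  # 0-based slice of (a.i2, b.i1) exclusive
            q_frag = q_seq[a.j2 : b.j1 - 1]
            if _shared_kmers(p_frag, q_frag, params.sim_kmer) < gap / params.kmer_divisor:
                parts.append([b])
                continue
        parts[-1].append(b)
    return parts


def trim_overlaps(cluster: list[SimplePair]) -> list[SimplePair]:
    """Trim adjacent seeds that overlap on either sequence.

    Adjacent seeds a, b overlap when i_a1 <= i_b1 <= i_a2 or
    j_a1 <= j_b1 <= j_a2 (tandem repeats with different copy numbers produce
    such seeds).  The overlap is chopped off the *preceding* seed, shortening
    it by the same amount on both sequences; seeds trimmed to nothing are
    dropped, and trimming cascades to the new predecessor.
    """
    out: list[SimplePair] = []
    for b in sort_by_query(cluster):
        skip_b = False
        while out:
            a = out[-1]
            if b.i1 < a.i1:
                # crossing seeds cannot be made co-linear by trimming;
                # keep the longer one (ties drop the preceding seed)
                if b.length < a.length:
                    skip_b = True
                    break
                out.pop()
                continue
            ov_i = a.i2 - b.i1 + 1 if a.i1 <= b.i1 <= a.i2 else 0
            ov_j = a.j2 - b.j1 + 1 if a.j1 <= b.j1 <= a.j2 else 0
            ov = max(ov_i, ov_j)
            if ov <= 0:
                break
            if ov >= a.length:
                out.pop()
                continue
            out[-1] = SimplePair(
                i1=a.i1,
                i2=a.i2 - ov,
                j1=a.j1,
                j2=a.j2 - ov,
                strand=a.strand,
                rec=a.rec,
                unique=a.unique,
            )
            break
        if not skip_b:
            out.append(b)
    return out


def fill_gaps(cluster: list[SimplePair]) -> SimilarRegion:
    """Insert normal pairs between adjacent seeds to make a region contiguous.

    For adjacent seeds ending at (i2q, j2q) and starting at (i2q+1', j2q+1'),
    a gap on the reference side becomes the fragment (i2q+1, i2q+1'-1) and
    likewise on the query side; an absent side is the empty-fragment sentinel
    (-1, -1).  No normal pair is inserted when the seeds are contiguous on
    both sequences.  Region-terminal sequence beyond the first/last seed is
    not extended: local alignments begin and end at seed boundaries.
    """
    ordered = sort_by_query(cluster)
    if not ordered:
        raise ValueError("cannot build a region from an empty cluster")
    pairs: list[Pair] = [ordered[0]]
    for a, b in zip(ordered, ordered[1:]):
        p_gap = b.i1 - a.i2 - 1
        q_gap = b.j1 - a.j2 - 1
        if p_gap < 0 or q_gap < 0:
            raise ValueError("fill_gaps requires a trimmed, non-overlapping cluster")
        if p_gap > 0 or q_gap > 0:
            pairs.append(
                NormalPair(
                    i1=a.i2 + 1 if p_gap > 0 else EMPTY,
                    i2=b.i1 - 1 if p_gap > 0 else EMPTY,
                    j1=a.j2 + 1 if q_gap > 0 else EMPTY,
                    j2=b.j1 - 1 if q_gap > 0 else EMPTY,
                )
            )
        pairs.append(b)
    first = ordered[0]
    return SimilarRegion(pairs=pairs, strand=first.strand, rec=first.rec)


def chain_pairs(
    pairs: list[SimplePair],
    p_seq: str,
    q_seq: str,
    params: SeedParams,
) -> list[SimilarRegion]:
    """Run the full chaining pipeline on the seeds of one (record, strand).

    ``q_seq`` must be the query in the frame the seeds were reported in
    (reverse-complemented for reverse-strand seeds).
    """
    regions: list[SimilarRegion] = []
    for cluster in cluster_by_posdiff(pairs, params):
        cleaned = remove_outliers(cluster, params)
        cleaned = resolve_duplicates(cleaned)
        for part in split_on_dissimilar_gaps(cleaned, p_seq, q_seq, params):
            trimmed = trim_overlaps(part)
            if trimmed:
                regions.append(fill_gaps(trimmed))
    return regions
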