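"""Gap closing: classify normal pairs and align them, then assemble regions.

Normal pairs fall into three types.  Equal-size fragment pairs whose
positional mismatch count stays under a threshold very likely contain only
substitutions, so the un-gapped alignment is already optimal (*Type I*).
Pairs with one empty side are pure indels (*Type II*).  Everything else
(*Type III*) is closed with a global affine-gap dynamic program constrained
to the fragment pair.  The complete alignment of a similar region is the
concatenation of the alignments of its simple and normal pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import OP_DEL, OP_INS, OP_MATCH, OP_MISMATCH, gotoh_global
from .chain import NormalPair, SimilarRegion
from .fmindex import FORWARD
from .genome import encode
from .seeds import SimplePair

logger = logging.getLogger(__name__)

# edit operations, CIGAR-flavoured: = match, X mismatch,
# I insertion in the query, D deletion from the reference
OP_CHARS = {OP_MATCH: "=", OP_MISMATCH: "X", OP_INS: "I", OP_DEL: "D"}
CONSUMES_P = {"=", "X", "D"}
CONSUMES_Q = {"=", "X", "I"}


@dataclass
class AlignParams:
    """Scoring scheme and Type-I acceptance threshold.

    Scores follow the usual affine convention: ``match`` is a bonus,
    ``mismatch``/``gap_open``/``gap_extend`` are positive penalties and a gap
    of length L costs ``gap_open + L * gap_extend``.  Keep ``gap_open``
    above ``mismatch``: otherwise one indel adjacent to a substitution ties
    with two indels split around it and the reported variant set becomes a
    tie-break artefact.  An equal-size normal
    pair is accepted as Type I (un-gapped) when its positional mismatch
    fraction is below ``type1_max_mismatch_frac`` (a single mismatch is
    always accepted).  ``band_width`` optionally restricts the DP to a
    diagonal band (widened automatically to the fragment length difference
    so a global path always exists); None computes the full matrix, which
    is affordable because chaining keeps fragments short.
    ``dp_cell_ceiling`` bounds the DP matrix size; larger problems are
    split proportionally and aligned piecewise.
    """

    match: int = 2
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 2
    type1_max_mismatch_frac: float = 0.3
    band_width: int | None = None
    dp_cell_ceiling: int = 16_000_000

    def __post_init__(self) -> None:
        if not 0 < self.type1_max_mismatch_frac < 1:
            raise ValueError("type1_max_mismatch_frac must be in (0, 1)")
        if self.gap_open < self.gap_extend or self.gap_extend < 0:
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class PairwiseAlignment:
    """Run-length encoded edit script between two fragments.

    ``ops`` is a list of (op, length) with op in {"=", "X", "I", "D"}.
    Reconstructing both fragments from the ops reproduces the inputs exactly;
    the score is the alignment's value under the generating scheme.
    """

    ops: list[tuple[str, int]]
    p_start: int = 1
    q_start: int = 1
    strand: str = FORWARD
    score: int = 0

    @property
    def p_span(self) -> int:
        return sum(n for op, n in self.ops if op in CONSUMES_P)

    @property
    def q_span(self) -> int:
        return sum(n for op, n in self.ops if op in CONSUMES_Q)

    @property
    def n_columns(self) -> int:
        return sum(n for _, n in self.ops)

    @property
    def n_matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    @property
    def identity(self) -> float:
        cols = self.n_columns
        return self.n_matches / cols if cols else 0.0

    def reconstruct(self, p_seq: str, q_seq: str) -> tuple[str, str]:
        """Render the two gapped rows from the underlying full sequences."""
        p_row: list[str] = []
        q_row: list[str] = []
        p = self.p_start - 1
        q = self.q_start - 1
        for op, n in self.ops:
            if op in ("=", "X"):
                p_row.append(p_seq[p : p + n])
                q_row.append(q_seq[q : q + n])
                p += n
                q += n
            elif op == "D":
                p_row.append(p_seq[p : p + n])
                q_row.append("-" * n)
                p += n
            else:
                p_row.append("-" * n)
                q_row.append(q_seq[q : q + n])
                q += n
        return "".join(p_row), "".join(q_row)


def _rle(op_codes: np.ndarray) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for code in op_codes:
        ch = OP_CHARS[int(code)]
        if ops and ops[-1][0] == ch:
            ops[-1] = (ch, ops[-1][1] + 1)
        else:
            ops.append((ch, 1))
    return ops


def score_ops(ops: list[tuple[str, int]], params: AlignParams) -> int:
    score = 0
    for op, n in ops:
        if op == "=":
            score += params.match * n
        elif op == "X":
            score -= params.mismatch * n
        else:
            score -= params.gap_open + params.gap_extend * n
    return score


def _fragments(np_: NormalPair, p_seq: str, q_seq: str) -> tuple[str, str]:
    p_frag = "" if np_.p_empty else p_seq[np_.i1 - 1 : np_.i2]
    q_frag = "" if np_.q_empty else q_seq[np_.j1 - 1 : np_.j2]
    return p_frag, q_frag


def classify_normal_pair(
    np_: NormalPair, p_seq: str, q_seq: str, params: AlignParams
) -> str:
    """Assign the Type I/II/III label (also stored on the pair)."""
    if np_.p_empty and np_.q_empty:
        raise ValueError("normal pair with both sides empty")
    if np_.p_empty or np_.q_empty:
        np_.ptype = "II"
        return "II"
    if np_.p_len == np_.q_len:
        p_frag, q_frag = _fragments(np_, p_seq, q_seq)
        mismatches = sum(a != b or a == "N" for a, b in zip(p_frag, q_frag))
        if mismatches <= 1 or mismatches < params.type1_max_mismatch_frac * np_.p_len:
            np_.ptype = "I"
            return "I"
    np_.ptype = "III"
    return "III"


def align_type1(np_: NormalPair, p_seq: str, q_seq: str,
                params: AlignParams | None = None) -> PairwiseAlignment:
    """Un-gapped alignment of an equal-size fragment pair."""
    if np_.p_len != np_.q_len:
        raise ValueError("Type I requires equal-size fragments")
    params = params or AlignParams()
    p_frag, q_frag = _fragments(np_, p_seq, q_seq)
    ops: list[tuple[str, int]] = []
    for a, b in zip(p_frag, q_frag):
        ch = "=" if (a == b and a != "N") else "X"
        if ops and ops[-1][0] == ch:
            ops[-1] = (ch, ops[-1][1] + 1)
        else:
            ops.append((ch, 1))
    return PairwiseAlignment(
        ops=ops, p_start=np_.i1, q_start=np_.j1, score=score_ops(ops, params)
    )


def align_type2(np_: NormalPair, params: AlignParams | None = None) -> PairwiseAlignment:
    """Pure indel: a single gap op spanning the non-empty side."""
    params = params or AlignParams()
    if np_.p_empty == np_.q_empty:
        raise ValueError("Type II requires exactly one empty side")
    if np_.p_empty:
        ops = [("I", np_.q_len)]
    else:
        ops = [("D", np_.p_len)]
    return PairwiseAlignment(
        ops=ops, p_start=np_.i1, q_start=np_.j1, score=score_ops(ops, params)
    )


# Tie-break weight: scores are scaled by _W and one extra unit is charged per
# mismatch, so among equal-score alignments the one with fewest mismatch
# columns wins (truth-like long gaps beat mismatch-dense re-alignments).
# _W must exceed any possible mismatch-count difference, i.e. the fragment
# length bound implied by dp_cell_ceiling.
_W = 4096


def _gotoh_chunked(p_codes: np.ndarray, q_codes: np.ndarray, params: AlignParams):
    """Piecewise DP for fragment pairs above the cell ceiling.

    The longer dimension is halved and the other split proportionally; the
    halves are aligned independently and concatenated.  This keeps memory
    bounded at the cost of optimality around the split point — such pairs are
    far outside the sizes chaining normally produces, so this path is logged.
    """
    n, m = len(p_codes), len(q_codes)
    if n * m <= params.dp_cell_ceiling:
        band = -1
        if params.band_width is not None:
            band = max(params.band_width, abs(n - m))
        return gotoh_global(
            p_codes, q_codes, _W * params.match, _W * params.mismatch + 1,
            _W * params.gap_open, _W * params.gap_extend, band,
        )
    logger.warning(
        "fragment pair %d x %d exceeds DP cell ceiling; aligning piecewise", n, m
    )
    half_n = n // 2
    half_m = round(m * half_n / n)
    s1, ops1 = _gotoh_chunked(p_codes[:half_n], q_codes[:half_m], params)
    s2, ops2 = _gotoh_chunked(p_codes[half_n:], q_codes[half_m:], params)
    return s1 + s2, np.concatenate([ops1, ops2])


def align_type3(
    np_: NormalPair, p_seq: str, q_seq: str, params: AlignParams
) -> PairwiseAlignment:
    """Global affine-gap alignment of a general fragment pair."""
    p_frag, q_frag = _fragments(np_, p_seq, q_seq)
    if not p_frag or not q_frag:
        raise ValueError("Type III requires both fragments non-empty")
    _, op_codes = _gotoh_chunked(encode(p_frag), encode(q_frag), params)
    ops = _rle(op_codes)
    return PairwiseAlignment(
        ops=ops, p_start=np_.i1, q_start=np_.j1, score=score_ops(ops, params)
    )


def align_normal_pair(
    np_: NormalPair, p_seq: str, q_seq: str, params: AlignParams
) -> PairwiseAlignment:
    ptype = np_.ptype or classify_normal_pair(np_, p_seq, q_seq, params)
    if ptype == "I":
        return align_type1(np_, p_seq, q_seq, params)
    if ptype == "II":
        return align_type2(np_, params)
    return align_type3(np_, p_seq, q_seq, params)


def assemble_region(
    region: SimilarRegion,
    p_seq: str,
    q_seq: str,
    params: AlignParams | None = None,
    aligned: dict[int, PairwiseAlignment] | None = None,
) -> PairwiseAlignment:
    """Concatenate per-pair alignments into the region's local alignment.

    Simple pairs contribute all-match runs; normal pairs are aligned on
    demand (or taken from ``aligned``, keyed by position in ``region.pairs``,
    when the caller computed them elsewhere — per-pair alignments are
    independent, so any computation order gives the same result).
    """
    params = params or AlignParams()
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    total = 0
    for idx, pair in enumerate(region.pairs):
        if isinstance(pair, SimplePair):
            push("=", pair.length)
            total += params.match * pair.length
        else:
            sub = (
                aligned[idx]
                if aligned is not None and idx in aligned
                else align_normal_pair(pair, p_seq, q_seq, params)
            )
            for op, n in sub.ops:
                push(op, n)
            total += sub.score

    aln = PairwiseAlignment(
        ops=ops,
        p_start=region.p_start,
        q_start=region.q_start,
        strand=region.strand,
        score=total,
    )
    if aln.p_span != region.p_end - region.p_start + 1:
        raise ValueError("assembled alignment does not cover the region's P span")
    if aln.q_span != region.q_end - region.q_start + 1:
        raise ValueError("assembled alignment does not cover the region's Q span")
    return aln
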