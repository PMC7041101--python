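"""Precision/recall evaluation of called variants against a truth set.

An SNV call is true when chromosome, coordinate and alleles match a truth
event exactly.  An indel call is true when a truth event of the same kind
and size lies within 10 bases of the predicted coordinate; the window makes
the measure insensitive to placement within the local repeat context, where
an indel put at either end of a tandem repeat or homopolymer is the same
event (the alignments ``AGCAT----TG`` and ``AG----CATTG`` describe one
deletion — :func:`indels_equivalent` tests that relation directly).
Matching is one-to-one, greedy by distance with ties to the left, so no
truth event is counted twice.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .genome import Genome
from .variants import SNV, Variant

INDEL_WINDOW = 10  # coordinate tolerance, inclusive, between anchor positions


@dataclass
class ClassResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        called = self.tp + self.fp
        return self.tp / called if called else None

    @property
    def recall(self) -> float | None:
        truths = self.tp + self.fn
        return self.tp / truths if truths else None


@dataclass
class EvalResult:
    snv: ClassResult
    indel: ClassResult


def indels_equivalent(ref_seq: str, a: Variant, b: Variant) -> bool:
    """True when the two indels produce the same local haplotype.

    Both events are replayed on the reference over the window covering both;
    identical results mean the events differ only by placement within a
    repeat context.
    """
    if a.kind != b.kind or a.net_size != b.net_size:
        return False
    lo = min(a.pos, b.pos)
    hi = max(a.end, b.end)
    window = ref_seq[lo - 1 : hi]

    def replay(v: Variant) -> str:
        off = v.pos - lo  # 0-based offset of the anchor within the window
        return window[:off] + v.alt + window[off + len(v.ref) :]

    return replay(a) == replay(b)


def _check_disjoint(truth: list[Variant]) -> None:
    by_chrom: dict[str, list[Variant]] = {}
    for v in sorted(truth, key=Variant.sort_key):
        by_chrom.setdefault(v.chrom, []).append(v)
    for events in by_chrom.values():
        for a, b in zip(events, events[1:]):
            if b.pos <= a.end:
                raise ValueError(
                    f"overlapping truth events at {a.chrom}:{a.pos} and {b.chrom}:{b.pos}"
                )


def evaluate_calls(
    called: list[Variant],
    truth: list[Variant],
    reference: Genome | list[Genome],
) -> EvalResult:
    """Score called variants against a disjoint truth set, per class."""
    genomes = [reference] if isinstance(reference, Genome) else list(reference)
    ref_seqs = {g.name: g.seq for g in genomes}
    _check_disjoint(truth)

    called_snv = [v for v in called if v.kind == SNV]
    truth_snv = [v for v in truth if v.kind == SNV]
    called_ind = [v for v in called if v.kind != SNV]
    truth_ind = [v for v in truth if v.kind != SNV]

    # --- SNVs: exact coordinate + alleles, one-to-one
    truth_by_site: dict[tuple[str, int], Variant] = {
        (v.chrom, v.pos): v for v in truth_snv
    }
    snv_tp = 0
    for v in called_snv:
        t = truth_by_site.get((v.chrom, v.pos))
        if t is not None and t.ref == v.ref and t.alt == v.alt:
            snv_tp += 1
            del truth_by_site[(v.chrom, v.pos)]
    snv = ClassResult(
        tp=snv_tp, fp=len(called_snv) - snv_tp, fn=len(truth_snv) - snv_tp
    )

    # --- indels: windowed, shift-equivalent, greedy nearest (ties left)
    truth_sorted = sorted(truth_ind, key=Variant.sort_key)
    called_sorted = sorted(called_ind, key=Variant.sort_key)
    truth_pos: dict[str, list[int]] = {}
    truth_at: dict[str, list[Variant]] = {}
    for t in truth_sorted:
        truth_pos.setdefault(t.chrom, []).append(t.pos)
        truth_at.setdefault(t.chrom, []).append(t)

    cand = []  # (distance, truth pos, called pos, called id, truth key)
    for ci, c in enumerate(called_sorted):
        seq = ref_seqs.get(c.chrom)
        pos_list = truth_pos.get(c.chrom)
        if seq is None or not pos_list:
            continue
        lo = bisect.bisect_left(pos_list, c.pos - INDEL_WINDOW)
        hi = bisect.bisect_right(pos_list, c.pos + INDEL_WINDOW)
        for ti in range(lo, hi):
            t = truth_at[c.chrom][ti]
            if c.kind == t.kind and c.net_size == t.net_size:
                cand.append((abs(c.pos - t.pos), t.pos, c.pos, ci, (c.chrom, ti)))
    cand.sort()
    used_called: set[int] = set()
    used_truth: set[tuple[str, int]] = set()
    ind_tp = 0
    for _, _, _, ci, tkey in cand:
        if ci in used_called or tkey in used_truth:
            continue
        used_called.add(ci)
        used_truth.add(tkey)
        ind_tp += 1
    indel = ClassResult(
        tp=ind_tp, fp=len(called_ind) - ind_tp, fn=len(truth_ind) - ind_tp
    )
    return EvalResult(snv=snv, indel=indel)
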