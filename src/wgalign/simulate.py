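"""Benchmark genome mutator: plant SNVs and indels at fixed per-Mbp rates.

The default profile plants 20,000 substitutions, 350 small indels (1-10 bp)
and 100 large indels (11-20 bp) per million bases; the 3x/5x presets triple
or quintuple only the SNV rate.  Events are placed uniformly over non-N
sites, with enough untouched sequence between them that the truth edit
script stays identifiable: two gaps merge into one strictly better-scoring
gap when fewer than ``gap_open / gap_extend`` matched bases separate them,
and an insertion/deletion pair collapses into a run of mismatches when the
matched stretch between them is shorter than roughly ``(gap_open +
indel_size) / 3`` bases (three quarters of randomly realigned columns
mismatch).  Events closer than those horizons are unrecoverable from the
sequences by *any* score-optimal aligner, so the simulator keeps 5 bases
between any two events and 25 between two indels (comfortably past the
horizon for sizes up to 20), which distorts uniformity negligibly at the
default densities.  Replaying the truth script on the template reproduces
the mutated genome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome
from .variants import DEL, INS, SNV, Variant, apply_variants

_BASES = "ACGT"


@dataclass
class MutationProfile:
    """Event rates per 1 Mbp and the RNG seed used to draw them."""

    snv_per_mb: float = 20_000.0
    small_indel_per_mb: float = 350.0
    large_indel_per_mb: float = 100.0
    seed: int = 0
    min_separation: int = 5  # untouched bases between any two events
    indel_separation: int = 25  # untouched bases between two indels

    SMALL_RANGE = (1, 10)
    LARGE_RANGE = (11, 20)

    def __post_init__(self) -> None:
        if min(self.snv_per_mb, self.small_indel_per_mb, self.large_indel_per_mb) < 0:
            raise ValueError("mutation rates must be nonnegative")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "MutationProfile":
        factor = {"1x": 1, "3x": 3, "5x": 5}.get(name.lower())
        if factor is None:
            raise ValueError(f"unknown preset {name!r} (use 1x, 3x or 5x)")
        return cls(snv_per_mb=20_000.0 * factor, seed=seed)


def random_genome(length: int, seed: int = 0, name: str = "chr1") -> Genome:
    """Uniform-random nucleotide sequence (no N), suitable as a template."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return Genome(name, seq)


class _SortedIntervals:
    """Append-in-batches interval set with sorted-array conflict queries."""

    def __init__(self) -> None:
        self.starts = np.empty(0, dtype=np.int64)
        self.ends = np.empty(0, dtype=np.int64)

    def clear_at(self, pos: int, span: int, gap: int) -> bool:
        k = int(np.searchsorted(self.starts, pos))
        if k > 0 and self.ends[k - 1] >= pos - gap:
            return False
        if k < len(self.starts) and self.starts[k] <= pos + span + gap:
            return False
        return True

    def extend(self, starts: list[int], ends: list[int]) -> None:
        self.starts = np.concatenate([self.starts, np.asarray(starts, dtype=np.int64)])
        self.ends = np.concatenate([self.ends, np.asarray(ends, dtype=np.int64)])
        order = np.argsort(self.starts, kind="stable")
        self.starts = self.starts[order]
        self.ends = self.ends[order]


def _place_events(
    rng: np.random.Generator,
    template: str,
    spans: list[int],
    is_indel: list[bool],
    min_gap: int = 5,
    indel_gap: int = 25,
) -> list[int]:
    """Choose a non-overlapping anchor position for each requested span.

    An event with span ``s`` occupies the 1-based interval [pos, pos + s];
    accepted events keep at least ``min_gap`` free bases between occupied
    intervals (``indel_gap`` between two indels) and avoid N anywhere in the
    window.  One candidate position is drawn per pending event each round
    and candidates are accepted in a left-to-right sweep; unplaced events
    retry next round.  Deterministic in ``rng``; returns positions in
    request order.
    """
    L = len(template)
    max_span = max(spans, default=0)
    if L < max_span + 4:
        raise ValueError("template too short to host the requested events")
    n_prefix = np.zeros(L + 1, dtype=np.int64)
    n_prefix[1:] = np.cumsum(
        np.frombuffer(template.encode(), dtype=np.uint8) == ord("N")
    )

    positions = [0] * len(spans)
    all_events = _SortedIntervals()
    indels = _SortedIntervals()
    pending = list(range(len(spans)))
    rounds = 0
    while pending:
        rounds += 1
        if rounds > 2000:
            raise ValueError(
                "template too short (or too N-rich) to host the requested events"
            )
        cand = rng.integers(2, L - max_span, size=len(pending))
        order = np.argsort(cand, kind="stable")
        # sweep in position order; track this round's acceptances locally
        last_end = -(10**9)
        last_indel_end = -(10**9)
        new_s: list[int] = []
        new_e: list[int] = []
        new_is: list[int] = []
        new_ie: list[int] = []
        still: list[int] = []
        for oi in order:
            req = pending[oi]
            pos = int(cand[oi])
            span = spans[req]
            ok = (
                n_prefix[pos + span] - n_prefix[pos - 1] == 0
                and pos - last_end > min_gap
                and all_events.clear_at(pos, span, min_gap)
                and (
                    not is_indel[req]
                    or (
                        pos - last_indel_end > indel_gap
                        and indels.clear_at(pos, span, indel_gap)
                    )
                )
            )
            if ok:
                positions[req] = pos
                last_end = pos + span
                new_s.append(pos)
                new_e.append(pos + span)
                if is_indel[req]:
                    last_indel_end = pos + span
                    new_is.append(pos)
                    new_ie.append(pos + span)
            else:
                still.append(req)
        if new_s:
            all_events.extend(new_s, new_e)
        if new_is:
            indels.extend(new_is, new_ie)
        pending = still
    return positions


def mutate_genome(
    template: Genome, profile: MutationProfile
) -> tuple[Genome, list[Variant]]:
    """Plant variants on ``template`` and return the mutated genome + truth.

    Event counts are the per-Mbp rates scaled by the template length
    (rounded); SNV alternates differ from the reference; indel sizes are
    uniform over the class ranges with insertions and deletions equally
    likely.  The truth list is the exact edit script in VCF conventions,
    sorted by coordinate.
    """
    rng = np.random.default_rng(profile.seed)
    L = len(template)
    if L == 0:
        raise ValueError("empty template")
    scale = L / 1e6
    n_snv = round(profile.snv_per_mb * scale)
    n_small = round(profile.small_indel_per_mb * scale)
    n_large = round(profile.large_indel_per_mb * scale)

    events: list[tuple[str, int]] = [(SNV, 0)] * n_snv
    for count, (lo, hi) in (
        (n_small, MutationProfile.SMALL_RANGE),
        (n_large, MutationProfile.LARGE_RANGE),
    ):
        sizes = rng.integers(lo, hi + 1, size=count)
        is_del = rng.random(count) < 0.5
        events.extend(
            (DEL if d else INS, int(s)) for s, d in zip(sizes, is_del)
        )

    # interleave classes so position acceptance order is not class-biased
    perm = rng.permutation(len(events))
    events = [events[i] for i in perm]
    spans = [size if kind == DEL else 0 for kind, size in events]
    is_indel = [kind != SNV for kind, _ in events]
    positions = _place_events(
        rng,
        template.seq,
        spans,
        is_indel,
        profile.min_separation,
        profile.indel_separation,
    )

    seq = template.seq
    name = template.name
    truth: list[Variant] = []
    for (kind, size), pos in zip(events, positions):
        ref_base = seq[pos - 1]
        if kind == SNV:
            choices = [b for b in _BASES if b != ref_base]
            truth.append(Variant(SNV, name, pos, ref_base, choices[int(rng.integers(0, 3))]))
        elif kind == DEL:
            truth.append(Variant(DEL, name, pos, seq[pos - 1 : pos + size], ref_base))
        else:
            ins = "".join(_BASES[c] for c in rng.integers(0, 4, size=size))
            truth.append(Variant(INS, name, pos, ref_base, ref_base + ins))

    truth.sort(key=Variant.sort_key)
    mutated = Genome(template.name, apply_variants(seq, truth))
    return mutated, truth
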