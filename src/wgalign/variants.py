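"""Sequence variants: extraction from alignments, ASI, and VCF round-trip.

Variants are reported VCF-style: 1-based reference coordinates, and indels
left-anchored on the reference base preceding the event, which both alleles
share.  A linear scan of an assembled alignment yields one SNV per mismatch
column and one insertion/deletion per maximal gap run.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .genome import Genome
from .pairalign import PairwiseAlignment

SNV = "SNV"
INS = "INS"
DEL = "DEL"


@dataclass(frozen=True)
class Variant:
    kind: str  # SNV | INS | DEL
    chrom: str
    pos: int  # 1-based; for indels the anchor base position
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind == SNV:
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError("SNV requires two different single-base alleles")
        elif self.kind == INS:
            if len(self.alt) <= len(self.ref) or self.ref[0] != self.alt[0]:
                raise ValueError("INS requires alt longer than ref, shared anchor")
        elif self.kind == DEL:
            if len(self.ref) <= len(self.alt) or self.ref[0] != self.alt[0]:
                raise ValueError("DEL requires ref longer than alt, shared anchor")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def net_size(self) -> int:
        """Mismatch contribution: 1 for an SNV, the indel size otherwise."""
        return 1 if self.kind == SNV else abs(len(self.ref) - len(self.alt))

    @property
    def end(self) -> int:
        """Last reference base covered (== pos for SNV at length 1 ref)."""
        return self.pos + len(self.ref) - 1

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.kind, self.ref, self.alt)


def call_variants(
    alignment: PairwiseAlignment,
    p_seq: str,
    q_seq: str,
    chrom: str = "ref",
) -> list[Variant]:
    """Scan an assembled alignment and emit its variants in coordinate order.

    One SNV per mismatch column; each maximal insertion (gap on the
    reference row) or deletion (gap on the query row) becomes a single
    anchored indel.  Applying the returned variants to the reference over the
    aligned span reproduces the query fragment.
    """
    out: list[Variant] = []
    p = alignment.p_start
    q = alignment.q_start
    for op, n in alignment.ops:
        if op == "=":
            p += n
            q += n
        elif op == "X":
            for o in range(n):
                ref_base = p_seq[p + o - 1]
                alt_base = q_seq[q + o - 1]
                if ref_base != alt_base:  # N-vs-N columns are not variants
                    out.append(Variant(SNV, chrom, p + o, ref_base, alt_base))
            p += n
            q += n
        elif op == "I":
            anchor = p_seq[p - 2]
            out.append(Variant(INS, chrom, p - 1, anchor, anchor + q_seq[q - 1 : q + n - 1]))
            q += n
        else:  # D
            anchor = p_seq[p - 2]
            out.append(Variant(DEL, chrom, p - 1, anchor + p_seq[p - 1 : p + n - 1], anchor))
            p += n
    out.sort(key=Variant.sort_key)
    return out


def apply_variants(seq: str, variants: list[Variant], start: int = 1, end: int | None = None) -> str:
    """Replay an edit script over ``seq[start..end]`` (1-based inclusive).

    Variants must be coordinate-sorted and non-overlapping, and fall inside
    the span (indel anchors may sit on ``start`` itself).
    """
    end = len(seq) if end is None else end
    parts: list[str] = []
    cur = start  # next unconsumed 1-based position
    for v in sorted(variants, key=Variant.sort_key):
        if v.pos < cur:
            raise ValueError(f"overlapping or unsorted variant at {v.chrom}:{v.pos}")
        parts.append(seq[cur - 1 : v.pos - 1])
        if v.kind == SNV:
            parts.append(v.alt)
            cur = v.pos + 1
        else:
            parts.append(v.alt)
            cur = v.pos + len(v.ref)
    parts.append(seq[cur - 1 : end])
    return "".join(parts)


def compute_asi(truth: list[Variant], genome_size: int) -> float:
    """Average sequence identity implied by a variant set, as a percentage.

    Total mismatches over the number of nucleobases, where an SNV contributes
    one mismatch and an indel of net size n contributes n.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    mismatches = sum(v.net_size for v in truth)
    return 100.0 * (1.0 - mismatches / genome_size)


# ---------------------------------------------------------------------- VCF

VCF_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


def write_vcf(variants: list[Variant], contigs: dict[str, int], sink) -> None:
    """Write a minimal VCF v4.2 with contig headers (positions 1-based).

    ``sink`` is a writable text handle or a path; variants referencing a
    contig absent from ``contigs`` are rejected.
    """
    own = isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__")
    fh = open(sink, "w") if own else sink
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=wgalign\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(VCF_HEADER + "\n")
        for v in sorted(variants, key=Variant.sort_key):
            if v.chrom not in contigs:
                raise ValueError(f"variant references unknown contig {v.chrom!r}")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")
    finally:
        if own:
            fh.close()


def read_vcf(path) -> list[Variant]:
    """Read a conformant VCF into variants, classifying by allele lengths."""
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref.upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if not set(ref + alt) <= set("ACGTN"):
                    continue  # symbolic or breakend records are not ours
                if len(ref) == 1 and len(alt) == 1:
                    kind = SNV
                elif len(alt) > len(ref):
                    kind = INS
                else:
                    kind = DEL
                out.append(Variant(kind, rec.chrom, rec.pos, ref, alt))
    out.sort(key=Variant.sort_key)
    return out


def contig_table(genomes: list[Genome]) -> dict[str, int]:
    return {g.name: len(g) for g in genomes}
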