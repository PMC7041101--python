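"""MAF output of region alignments (plus a BLAST-like pretty rendering).

MAF "s" line convention: start is 0-based; for reverse-strand rows the start
is relative to the reverse-complemented source sequence.  Internal
coordinates are 1-based inclusive, and reverse-strand regions already carry
query coordinates in the reverse-complement frame, so the conversion is a
plain ``start - 1``.
"""

from __future__ import annotations

from .fmindex import REVERSE
from .genome import Genome, revcomp


def write_maf(result, references: list[Genome], queries: list[Genome], sink) -> None:
    """Write one MAF block per region alignment."""
    ref_by_name = {g.name: g for g in references}
    qry_by_name = {g.name: g for g in queries}
    sink.write("##maf version=1 program=wgalign\n")
    for ra in result.regions:
        ref = ref_by_name[ra.ref_name]
        qry = qry_by_name[ra.query_name]
        q_seq = qry.seq if ra.strand != REVERSE else revcomp(qry.seq)
        p_row, q_row = ra.alignment.reconstruct(ref.seq, q_seq)
        aln = ra.alignment
        sink.write(f"a score={aln.score}\n")
        sink.write(
            f"s {ref.name} {aln.p_start - 1} {aln.p_span} + {len(ref)} {p_row}\n"
        )
        sink.write(
            f"s {qry.name} {aln.q_start - 1} {aln.q_span} {ra.strand} {len(qry)} {q_row}\n"
        )
        sink.write("\n")


def write_pretty(result, references: list[Genome], queries: list[Genome], sink,
                 width: int = 60) -> None:
    """Human-readable pairwise rendering with match bars."""
    ref_by_name = {g.name: g for g in references}
    qry_by_name = {g.name: g for g in queries}
    for ra in result.regions:
        ref = ref_by_name[ra.ref_name]
        qry = qry_by_name[ra.query_name]
        q_seq = qry.seq if ra.strand != REVERSE else revcomp(qry.seq)
        p_row, q_row = ra.alignment.reconstruct(ref.seq, q_seq)
        sink.write(
            f"# {ref.name}:{ra.region.p_start}-{ra.region.p_end} vs "
            f"{qry.name}:{ra.region.q_start}-{ra.region.q_end} ({ra.strand}) "
            f"identity={ra.identity:.4f} score={ra.alignment.score}\n"
        )
        bars = "".join(
            "|" if a == b and a != "-" else " " for a, b in zip(p_row, q_row)
        )
        for i in range(0, len(p_row), width):
            sink.write(f"  {p_row[i : i + width]}\n")
            sink.write(f"  {bars[i : i + width]}\n")
            sink.write(f"  {q_row[i : i + width]}\n\n")
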