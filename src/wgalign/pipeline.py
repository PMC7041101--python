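"""End-to-end orchestration: seed -> chain -> align -> variants/outputs.

``align_genomes`` runs the whole pipeline on in-memory genomes and returns
region alignments plus variants; ``run_alignment`` is the file-facing
wrapper used by the CLI.  Output is deterministic and independent of the
thread/block count: seeding is partitioned into blocks (the multithreading
unit) whose merged results are canonically ordered and deduplicated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

from .chain import NormalPair, SimilarRegion, chain_pairs
from .fmindex import FORWARD, REVERSE, ReferenceIndex, build_index
from .genome import Genome, revcomp
from .pairalign import AlignParams, PairwiseAlignment, assemble_region
from .seeds import SeedParams, SimplePair, find_lmems
from .variants import Variant, call_variants

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of one run; serializable so a run can be reproduced."""

    seed: SeedParams = field(default_factory=SeedParams)
    align: AlignParams = field(default_factory=AlignParams)
    threads: int = 1
    min_identity: float = 0.0  # report everything by default
    write_maf: bool = True
    write_vcf: bool = True
    write_dotplot: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["seed"] = SeedParams(**d.get("seed", {}))
        d["align"] = AlignParams(**d.get("align", {}))
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RegionAlignment:
    """One reported local alignment with its provenance."""

    ref_name: str
    query_name: str
    strand: str
    region: SimilarRegion
    alignment: PairwiseAlignment
    identity: float


@dataclass
class AlignmentResult:
    regions: list[RegionAlignment]
    variants: list[Variant]


def align_genomes(
    references: Genome | list[Genome],
    queries: Genome | list[Genome],
    config: RunConfig | None = None,
    index: ReferenceIndex | None = None,
) -> AlignmentResult:
    """Align every query record against the reference set.

    Variants are extracted from forward-strand regions; reverse-strand
    (inverted) regions are reported as alignments only.  The result is
    independent of ``config.threads``.
    """
    config = config or RunConfig()
    refs = [references] if isinstance(references, Genome) else list(references)
    qrys = [queries] if isinstance(queries, Genome) else list(queries)
    for g in qrys:
        g.validate()
    if index is None:
        index = build_index(refs)

    regions_out: list[RegionAlignment] = []
    variants: list[Variant] = []
    for query in qrys:
        pairs = find_lmems(index, query, config.seed, n_blocks=max(1, config.threads))
        logger.info("query %s: %d simple pairs", query.name, len(pairs))
        q_fwd = query.seq
        q_rev = revcomp(q_fwd)

        by_group: dict[tuple[int, str], list[SimplePair]] = {}
        for s in pairs:
            by_group.setdefault((s.rec, s.strand), []).append(s)

        n_regions = 0
        type_tally = {"I": 0, "II": 0, "III": 0}
        for (rec, strand), group in sorted(by_group.items()):
            p_seq = refs[rec].seq
            q_seq = q_fwd if strand == FORWARD else q_rev
            for region in chain_pairs(group, p_seq, q_seq, config.seed):
                aln = assemble_region(region, p_seq, q_seq, config.align)
                for pair in region.pairs:
                    if isinstance(pair, NormalPair):
                        type_tally[pair.ptype] += 1
                identity = aln.identity
                if identity < config.min_identity:
                    continue
                n_regions += 1
                regions_out.append(
                    RegionAlignment(
                        ref_name=refs[rec].name,
                        query_name=query.name,
                        strand=strand,
                        region=region,
                        alignment=aln,
                        identity=identity,
                    )
                )
                if strand == FORWARD:
                    variants.extend(
                        call_variants(aln, p_seq, q_seq, chrom=refs[rec].name)
                    )
        logger.info(
            "query %s: %d regions, normal pairs I/II/III = %d/%d/%d",
            query.name,
            n_regions,
            type_tally["I"],
            type_tally["II"],
            type_tally["III"],
        )

    variants.sort(key=Variant.sort_key)
    return AlignmentResult(regions=regions_out, variants=variants)


def run_alignment(
    ref_path,
    query_path,
    out_prefix: str,
    config: RunConfig | None = None,
    index_path=None,
) -> AlignmentResult:
    """File-level pipeline: FASTA in, MAF/VCF/dot-plot out (per config)."""
    from .dotplot import export_dotplot
    from .genome import read_fasta
    from .mafio import write_maf
    from .variants import contig_table, write_vcf

    config = config or RunConfig()
    refs = read_fasta(ref_path)
    qrys = read_fasta(query_path)
    index = ReferenceIndex.load(index_path) if index_path else None
    result = align_genomes(refs, qrys, config, index=index)

    if config.write_maf:
        with open(f"{out_prefix}.maf", "w") as fh:
            write_maf(result, refs, qrys, fh)
    if config.write_vcf:
        write_vcf(result.variants, contig_table(refs), f"{out_prefix}.vcf")
    if config.write_dotplot:
        with open(f"{out_prefix}.dotplot.tsv", "w") as fh:
            export_dotplot(result, fh)
    return result
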