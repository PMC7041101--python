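"""Benchmark round trip: mutate, align, call, score.

Plants variants on a 1 Mbp random genome at the default 1X rates (20,000
SNVs, 350 small + 100 large indels per Mbp), prints the implied average
sequence identity (ASI: 1 - variant-induced mismatches / genome size),
recovers the variants by whole-genome alignment and scores them: SNVs
match on exact coordinate and alleles, indels on kind and size within a
10 bp window (placement inside a repeat is equivalent at either end).
"""

from wgalign import (
    MutationProfile,
    align_genomes,
    compute_asi,
    evaluate_calls,
    mutate_genome,
    random_genome,
)

template = random_genome(1_000_000, seed=7)
mutated, truth = mutate_genome(template, MutationProfile(seed=8))
print(f"planted {len(truth)} variants; ASI = {compute_asi(truth, len(template)):.2f}%")

result = align_genomes(template, mutated)
scores = evaluate_calls(result.variants, truth, template)

for name, cls in (("SNV", scores.snv), ("indel", scores.indel)):
    print(
        f"{name:5s} tp={cls.tp} fp={cls.fp} fn={cls.fn} "
        f"precision={cls.precision:.4f} recall={cls.recall:.4f}"
    )
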