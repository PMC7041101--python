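#!/bin/sh
# End-to-end shell workflow on a small simulated dataset.
#
# 1. simulate: plant variants on a reference at the 1x per-Mbp rates,
#    writing the mutated genome and the truth VCF
# 2. index: build and save the FM-index of the reference
# 3. align: seed-chain-align the mutated genome against the reference,
#    writing MAF alignments, a VCF of called variants and dot-plot segments
# 4. evaluate: precision/recall of the calls against the truth
set -e
workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

python - "$workdir" <<'PY'
import sys
from wgalign import random_genome, write_fasta
write_fasta([random_genome(200_000, seed=11)], sys.argv[1] + "/ref.fa")
PY

wgalign simulate "$workdir/ref.fa" --preset 1x --seed 5 \
    -o "$workdir/mut.fa" -v "$workdir/truth.vcf"
wgalign index "$workdir/ref.fa" -o "$workdir/ref"
wgalign -v align -r "$workdir/ref.fa" -q "$workdir/mut.fa" \
    --index "$workdir/ref.npz" -o "$workdir/out" --dotplot --threads 4
wgalign evaluate --truth "$workdir/truth.vcf" --calls "$workdir/out.vcf" \
    --ref "$workdir/ref.fa"
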