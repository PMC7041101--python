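"""Build an FM-index over a small genome and query it.

The index covers the reference and its reverse complement, so one backward
search reports occurrences on both strands; `locate` translates suffix-array
rows into 1-based positions with strands.
"""

from wgalign import Genome, build_index

genome = Genome("toy", "TTTTGAATTCTTTTACGTACGT")
index = build_index(genome)

for pattern in ("ACGT", "GAATTC", "GGGG"):
    rng = index.backward_search(pattern)
    hits = index.locate(rng, len(pattern))
    print(f"{pattern}: {rng.width} occurrence(s) -> {hits}")

# GAATTC is its own reverse complement, so it is reported on both strands
# at the same position; GGGG does not occur at all (empty range).
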