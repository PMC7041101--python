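"""Detect an inverted segment and export dot-plot segments.

The query carries the middle third of the reference reverse-complemented.
Seeding finds reverse-strand matches for that block; the long dissimilar
gap splits the forward chain, so three local alignments result: +, -, +.
The dot-plot table lists one segment per alignment (query on x, reference
on y); the inverted block appears as a negative-slope segment.
"""

import io

from wgalign import Genome, align_genomes, random_genome, revcomp
from wgalign.dotplot import export_dotplot

a = random_genome(4000, seed=1, name="a").seq
b = random_genome(4000, seed=2, name="b").seq
c = random_genome(4000, seed=3, name="c").seq

reference = Genome("ref", a + b + c)
query = Genome("qry", a + revcomp(b) + c)

result = align_genomes(reference, query)
buf = io.StringIO()
rows = export_dotplot(result, buf, {"qry": len(query)})
print(buf.getvalue().rstrip())
print(f"\n{len(rows)} segments; strands:",
      [row[-1] for row in rows])
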