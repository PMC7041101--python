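# Methods

This note documents the model behind `wgalign`, the parameters that
matter, the numerical choices, what the synthetic benchmark does and does
not establish, and the known limitations.

## Pipeline model

The aligner assumes two *intra-species* genomes: long stretches of exact
identity interrupted by point substitutions, small indels, and the
occasional larger-scale difference (dissimilar insertions, inversions).
That assumption drives every stage:

- **Seeding.** Exact matches are found with a backward-search FM-index
  over the reference concatenated with its reverse complement, so one scan
  covers both strands.  A *local maximal exact match* (LMEM) starts at a
  query position and extends until no indexed occurrence continues.  The
  scan is greedy and restarts at the mismatch position, so consecutive
  seeds tile the query except for short shadows after each difference.
  Because forward extension is implemented by prepending complements to a
  backward search, a hit in the reverse-complement half of the index is a
  forward-strand match and vice versa.
- **Chaining.** Co-linear seeds share `PosDiff = i1 − j1` up to the indel
  sizes between them.  Clustering sorts all seeds by PosDiff and breaks at
  sorted-adjacent gaps above `max_diff`; this is robust to cumulative
  PosDiff drift because a single indel moves PosDiff by at most its size,
  so genuinely co-linear seeds never produce a sorted gap above the
  largest single indel.  The query-order cleanups (outlier removal,
  duplicate resolution, dissimilar-gap splitting, overlap trimming, gap
  filling) turn a cluster into a contiguous region of simple and normal
  pairs.
- **Gap closing.** Equal-size fragment pairs with few positional
  mismatches are substitution runs (Type I) — the un-gapped alignment is
  optimal under the default scores, since one mismatch (−4) is cheaper
  than any gap pair (−16).  One-side-empty pairs are literal indels
  (Type II).  Only the remainder (Type III) pays for a full affine-gap DP,
  and those fragments are short by construction because `max_diff` bounds
  the indel size between adjacent anchors.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `k` | 30 | minimum LMEM length; ~1/4^30 chance random 30-mers collide, so seeds are near-unique in Mbp-scale genomes |
| `f` | 5 | maximum LMEM occurrence count; seeds in higher-copy repeats are uninformative |
| `stride` | 5 | restart offset of sensitive mode (denser seeding) |
| `max_diff` | 25 | PosDiff cluster break = largest indel bridged between adjacent seeds |
| `outlier_tol` | 5 | neighbour PosDiff tolerance of the outlier filter; terminal seeds use `max_diff` against their single neighbour |
| `gap_break` | 300 bp | inter-seed gap that triggers the similarity test |
| `sim_kmer`, `kmer_divisor` | 8, 3 | gap fragments sharing < gap/3 distinct 8-mers are dissimilar; 8-mers survive ~85% of columns at 2% divergence while random 600-mers share ~5 |
| match/mismatch | +2 / −4 | standard even-cost substitution trade-off |
| gap open/extend | 6 / 2 | `gap_open > mismatch` so an indel beside a substitution never ties with a split around it; length-L gap costs 6 + 2L |
| Type-I threshold | mismatches ≤ 1 or < 0.3·len | keeps substitution-dense equal-size pairs un-gapped; single-base SNV gaps are the dominant normal-pair class and must stay Type I |
| identity filter | 0.0 | report all local alignments |

## Numerical and tie-break choices

- **Lexicographic DP objective.** The gapped aligner maximizes the affine
  score and, among equal-score alignments, minimizes mismatch columns
  (penalties are scaled by 4096 with one extra unit per mismatch).
  Without this, a long-gap representation (e.g. an 18 bp insertion plus a
  9 bp deletion) can tie exactly with a mismatch-dense re-alignment and
  the traceback order, not the biology, decides which variants are
  reported.  Within a DP state, ties prefer diagonal over deletion over
  insertion, and gap extension over opening, so gaps open as far left as
  possible; determinism is exact.
- **Separators and LF mapping.** The indexed text keeps a unique smallest
  final terminator, so the lexicographic suffix order is a rotation order
  and the BWT's LF mapping reconstructs the text — a cheap global
  integrity check on the index arrays.  Record separators merely need to
  be unmatchable; no seed can span a junction.
- **Block-invariant seeding.** The query is scanned in blocks (the
  multithreading unit).  Each block records its full restart trajectory;
  merging follows the global trajectory exactly, single-stepping through
  the (rare, short) out-of-phase stretch after each block boundary before
  adopting the block's remaining seeds.  The seed set is therefore
  *identical* to a single-block scan for any block count — thread count
  can never change output.  Blocks are currently processed sequentially;
  the block structure is the parallelism contract, wall-clock scaling is
  not the point of this implementation.
- **Trimming cascades.** Overlap trimming shortens the preceding seed by
  the larger of the reference/query overlaps, dropping seeds trimmed to
  nothing and re-checking against the new predecessor; crossing seeds
  (not resolvable by trimming) keep the longer one.
- **Degenerate inputs.** Empty sequences and non-ACGTN symbols are
  rejected at the boundary; N never matches anything (including N), so
  seeds cannot enter N runs, and N-containing columns in closed gaps count
  as mismatches but are not reported as variants when both sides are N.
- **Oversize Type III pairs** (possible when seeds are sparse, e.g. very
  high divergence) fall back to a logged piecewise DP above a cell ceiling
  (default 16M cells) that splits fragments proportionally; optimality is
  local to each piece.

## The synthetic benchmark

`mutate_genome` emulates intra-species divergence at fixed rates: per Mbp,
20,000 substitutions plus 350 small (1–10 bp) and 100 large (11–20 bp)
indels, with 3x/5x presets scaling only the SNV rate; sizes uniform per
class, insertion/deletion equally likely, alternates uniform over the
other three bases.  Positions are uniform over non-N sites subject to
separation constraints, and the truth VCF is the exact edit script.

**Why events are separated.** The benchmark's premise is that the truth
script is recoverable from the sequences.  That fails if events sit inside
each other's *parsimony horizon*: two gaps separated by fewer than
`gap_open / gap_extend` matched bases merge into one strictly
better-scoring gap, and an insertion/deletion pair whose matched gap is
shorter than roughly `(gap_open + size) / 3` bases (three quarters of
randomly realigned columns mismatch) collapses into a mismatch run.  Any
score-optimal aligner — not just this one — reports the merged form.  The
simulator therefore keeps ≥ 5 untouched bases between any two events and
≥ 25 between two indels (past the horizon for sizes ≤ 20).  At the default
densities (one event per ~49 bp) this rejects ~2% of candidate placements
and leaves the process effectively uniform.  SNV separation must stay
small: at 5x (100,000 SNVs/Mbp) mean spacing is 10 bp, so a 25 bp SNV rule
would be geometrically infeasible.

**What passing does and does not show.**  Uniform-random genomes have no
long repeats, segmental duplications, N runs, or GC structure; seeds are
near-unique and chaining is easy.  The benchmark therefore validates the
*machinery* — index correctness, chain bookkeeping, DP optimality,
coordinate conventions, conservation — and the accuracy ceiling of the
seed-chain-align design at realistic variant densities.  It does not
predict accuracy in centromeres, satellite arrays, or other repeat-rich
regions of real genomes, where seed multiplicity and chain ambiguity
dominate.

**Known, accepted loss modes at 1x** (a few events per Mbp in total):
substitutions adjacent to an indel can be absorbed into an equivalent
shifted gap placement that scores strictly better (the truth substitution
is unrecoverable from sequence); and variants beyond the terminal seed of
a region are unreported, because local alignments start and end at seed
boundaries and are not extended into unanchored sequence.

**Problem sizes.**  The test suite runs the full round trip at 1 Mbp and
the acceptance benchmark at 5 Mbp (about half a minute of alignment);
multi-Mbp development batteries across nine seed pairs showed zero indel
errors and SNV recall ≥ 0.9999 at these sizes.

## Evaluation rules

SNVs match on exact (chromosome, position, alleles).  Indels match when a
truth event of the same kind and net size lies within 10 bp of the
predicted anchor (inclusive); the window makes the measure insensitive to
placement inside tandem repeats and homopolymers, where a gap at either
end of the repeat is the same event (`indels_equivalent` tests that
relation explicitly by replaying both events over the covering window).
Matching is one-to-one and greedy by distance with ties to the left, so a
truth event is never credited twice; swapping the called and truth roles
swaps precision and recall.  Undefined ratios (empty classes) are reported
as absent rather than zero.

## Limitations

- Variants are called from forward-strand regions only; inverted segments
  are reported as reverse-strand alignments (MAF, dot-plot) but their
  interior differences are not expressed as VCF rows.
- Region-terminal sequence before the first and after the last seed of a
  region is unaligned; no end extension is attempted.
- The index stores a full suffix array and full rank table (~20 bytes per
  indexed base); genomes far beyond the hundreds-of-Mbp scale would need a
  sampled index, which is out of scope.
- Haploid model throughout: no genotypes, phasing, or diploid
  reconciliation.
- The 5x preset stresses seeding (mean exact-segment length ~10 bp at 10%
  SNV density is far below the default `k`=30); matching the 1x accuracy
  there requires smaller `k`/sensitive mode and is not tuned for.
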