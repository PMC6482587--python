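# Methods

## Model and scope

`capricirc` analyses circRNAs from back-splice junction evidence. A
back-splice joins the 3′ end of a downstream segment (donor) to the 5′ start
of an upstream segment (acceptor) on the same strand; internally a circRNA is
the 0-based half-open genomic span `[acceptor, donor)`. All written files use
1-based inclusive coordinates. The package does not re-implement a
production spliced aligner: the split mapper is exact-anchor based and meant
for the small genomes the bundled generator produces; externally aligned
chimeric records can be imported instead.

## Read filtering

A read is removed iff (i) it contains a ≥ 12-nt prefix of a configured
adapter as an exact substring, (ii) its fraction of uncertain bases (N)
exceeds 5 %, or (iii) more than 20 % of its bases are below Q20. Rule (iii)
resolves an ambiguity in the usual "bases with q < 20" phrasing — a single
sub-Q20 base should not discard a read; the 20 % fraction is this package's
choice and both numbers are policy fields.

## Split-read detection

The two terminal `anchor_len`-mers (default 20 nt) of each read are looked up
in an exact k-mer index of the genome; reads whose anchors hit more than one
locus are discarded and counted (junction evidence must be unique). Reads
placing contiguously are counted as linear. Otherwise the two segments are
extended toward each other: the split point `s ∈ [anchor, L−anchor]` is
chosen to minimise total Hamming mismatches (computed with prefix sums).
Sequence identity around the joint makes the split point ambiguous and would
shift the junction off its splice signal, so among equally good splits the
one whose implied junction carries a GT/AG (or minus-strand AC..CT) signal is
preferred — the same realignment idea production circRNA callers use. Both
read orientations are tried; a chimera is *noncolinear* (back-splice
candidate) iff the second segment maps upstream of the first.

## Junction calling

Noncolinear chimeras are grouped by (chromosome, acceptor, donor) and a
junction is accepted iff all four criteria hold:

1. **Splice signal**: genomic `GT` immediately 3′ of the donor and `AG`
   immediately 5′ of the acceptor on the junction strand (reverse-complement
   logic on −). The signal also decides the reported strand. Window offsets
   are not configurable: the dinucleotides must be exactly adjacent.
2. **Mismatches**: ≤ 2 per supporting read (a read property, not a junction
   aggregate); dirty reads are excluded, not fatal.
3. **Support**: ≥ 1 remaining junction read (pooled over samples).
4. **Geometry**: both ends on the same chromosome, span ≤ 100 kb. The
   original phrasing of this criterion is ambiguous ("more than 2 splice
   sites … on the same chromosome"); it is implemented as same-chromosome
   plus the 100-kb span cap, which also excludes multi-chromosome fusions.

Every rejected candidate is logged with exactly the subset of criteria that
failed, and relaxing any criterion can only grow the call set (tested).

Origin classes: *exonic* iff both junction ends coincide exactly (± 0 nt)
with exon boundaries of one gene (spliced length = sum of enclosed exons);
*intronic* (ciRNA) iff the span lies inside one intron; *intergenic* iff the
span overlaps no gene. A span overlapping genes without an exact match is
assigned to the gene with the largest overlap (ties by gene id), exonic if it
touches an exon — never an error.

## Quantification

FPKM uses back-splice junction fragments only as numerator and the spliced
length as effective length; the library size is the sample's total mapped
fragments (linear + junction). This is a deliberate simplification: no
transcript-model estimation of circular isoforms is attempted, and whether
published FPKM denominators counted all mapped fragments is undocumented —
the choice is recorded here and in output metadata. Expression intervals are
half-open `[lo, hi)` with boundaries 0.1, 0.3, 3.57, 15, 60 (a value exactly
on a boundary belongs to the upper interval). Percentages are rounded half-up
to 2 decimals, matching table formatting.

## Differential expression

Group means are arithmetic means of per-sample FPKM. Fold changes are
oriented b-over-a (RE/PE in the reference design; published tables carry this
orientation even where the text says PE/RE). A zero mean in one group makes
the circRNA stage-specific with log₂fc = ±∞; both-zero circRNAs are excluded
from testing. Significance is a two-sided Fisher's exact test on
`[[count_a, count_b], [lib_a−count_a, lib_b−count_b]]` with replicate counts
pooled within groups — no replicate-aware dispersion model is attempted
because the design (2 × 2) cannot support one. The primary gate is raw
P < 0.05; a stricter BH q < 0.01 gate is available as a config switch.
Reported precision: linear fold 2 decimals, log₂fc 4 decimals.

## Host-gene enrichment

Upper-tail hypergeometric P with exact rational combinatorics for universes
N ≤ 2000 and `scipy.stats.hypergeom.sf` in log space beyond (the two paths
agree to 1e−10 where they overlap, tested). The default background universe
is all genes hosting ≥ 1 detected circRNA (the "genomic background" of the
detected set); a whole-annotation universe can be supplied. Correction is
Benjamini–Hochberg; namespaces are carried through and can be reported
separately.

## Sponge network

Seed matches are scanned on the sense sequence of each circRNA — spliced
exons for exonic calls, the genomic span otherwise — extended by the first
7 nt (max site length − 1) so every site on the circle, including
junction-spanning ones, is found exactly once (rotation invariance is
tested). Classes: 6mer (positions 2–7), 7mer-m8 (2–8), 7mer-A1 (2–7 + A
opposite position 1), 8mer. The external target-prediction programs are
replaced by this explicit seed-class matcher plus a transparent, ungapped
complementarity score over the miRNA 3′ region (+1 Watson-Crick, +0.5 G:U
wobble, −1 mismatch), because the original tools are named without
parameters. The duplex threshold defaults to `None` (keep every seed match);
any numeric threshold filters monotonically. Union of evidence is the
default interaction rule. The network is a bipartite `networkx` graph,
exported as edge list, SIF or GraphML.

## Synthetic data generator

The generator emulates what the analysis assumes about real libraries, not
the libraries themselves: single-end 100-nt reads at constant Q30 (the
insert-size behaviour of the original paired-end libraries around junctions
is unstated, so single-end junction reads are simulated), per-base mismatch
rate 0.001, 1 % adapter contamination on linear background reads (kept off
junction reads so the realized truth-count table is exact), 20,000 linear
reads per sample drawn from spliced transcripts, and junction reads Poisson
around the planted abundance with ≥ 20 nt on each side of the joint.
Exonic circRNAs are planted on internal exon runs so flanking introns supply
GT/AG naturally; intronic/intergenic plants patch the signal dinucleotides
just outside the span. Defaults: 2 chromosomes × 120 kb, 24 genes with 4–6
exons of 150–300 bp (≥ read length, so a read crosses at most one splice
boundary) and introns of 300–800 bp, GC 0.42; 50 circRNAs (30/10/10 by
class), non-differential abundance uniform 8–20 junction reads per sample,
10 differential circRNAs at 4 vs 32 (8-fold, both directions); 2 × 2 design
(PE1, PE2, RE1, RE2). Everything is seeded and byte-reproducible.

What passing tests therefore show: the caller is exact on clean, unique,
canonically spliced junctions and the statistics behave as specified. What
they do not show: robustness to indels, quality decay, repeats/multimapping,
non-canonical splice signals, or paired-end fragment effects — all out of
scope by design.

The demo's circRNA/host-gene correlation is near zero because the generator
draws circRNA abundance independently of host transcript level; the
correlation operator itself is tested against constructed and closed-form
inputs.

## Numerical choices and degenerate inputs

Percentages use half-up rounding (table convention) rather than banker's
rounding. Split ties prefer signal-bearing splits, then the smallest split
point. Fisher tests use `scipy.stats.fisher_exact` (validated against exact
rational margin enumeration to 1e−10 for pooled counts ≤ 30). Empty inputs
return empty outputs (header-only files, empty histograms); zero denominators
(library size, raw reads, spliced length, zero-variance correlation) raise
`ValueError` rather than propagating NaN.

## Problem sizes

Test and acceptance runs use the default scenario above (~83,000 reads over
four samples); a full pipeline run completes in a few seconds on one CPU,
and the whole test suite in well under a minute.
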