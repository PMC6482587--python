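# capricirc

Circular RNAs (circRNAs) are covalently closed transcripts produced by
back-splicing: the 3′ splice donor of a downstream exon is joined to the 5′
splice acceptor of an upstream exon. In RNA-seq data the diagnostic signature
is a read that maps on one chromosome in two segments in *noncolinear*
(back-spliced) order. `capricirc` is a desk-scale, fully tested
re-implementation of a circRNA profiling workflow of the kind used to compare
pre-receptive (PE, gestational day 5) and receptive (RE, day 15) goat
endometrium:

* **Synthetic data generator** — toy multi-gene genomes with canonical GT..AG
  introns on both strands, planted exonic/intronic/intergenic circRNAs with
  configurable two-condition abundances, and seeded junction-spanning reads —
  so the entire pipeline is testable with no downloads.
* **Junction calling** — read QC (adapters, N fraction, quality), an
  exact-anchor split-read mapper, and back-splice calling under four
  criteria: GT/AG splice signal at the junction, ≤ 2 mismatches per
  supporting read, ≥ 1 junction read, and both ends on the same chromosome
  within 100 kb. Origin classes (exonic, intronic/ciRNA, intergenic) and
  host genes are assigned from the annotation. External chimeric records
  (fusion TSV or SAM with SA tags) can be ingested instead of reads.
* **Quantification** — FPKM from junction fragments,
  `FPKM = reads · 10⁹ / (spliced length · library size)`, with the
  six-interval expression binning (boundaries 0.1, 0.3, 3.57, 15, 60) and
  length/origin distributions.
* **Differential expression** — group-mean FPKM, log₂(RE/PE) fold changes
  with ±∞ for stage-specific circRNAs, two-sided Fisher's exact test on
  pooled junction counts, Benjamini–Hochberg q-values, and the
  up/down × PE-specific/RE-specific/co-expressed partition.
* **Host-gene enrichment** — exact upper-tail hypergeometric
  over-representation of the DEC host genes against GO/KEGG-style
  term-to-gene maps (exact rational arithmetic for universes ≤ 2000 genes).
* **Sponge (ceRNA) network** — TargetScan-style seed-site classes (6mer,
  7mer-A1, 7mer-m8, 8mer) scanned on the *circularized* sequence so sites
  spanning the back-splice junction are found, an optional transparent duplex
  score over the miRNA 3′ region, and a bipartite circRNA–miRNA network
  exported as edge list / SIF / GraphML.

## Worked example

```bash
capricirc demo --outdir demo_out --seed 5
```

runs the full pipeline on the default synthetic scenario (2 chromosomes ×
120 kb, 24 genes, 50 planted circRNAs — 30 exonic / 10 intronic / 10
intergenic — of which 10 are 8-fold differential; 2 conditions × 2
replicates, 100-nt reads). It prints:

```
report written to demo_out/report.txt
circRNAs called: 50; DECs: 10
truth precision 1.000 recall 1.000
```

All 50 planted circRNAs are recovered at exact coordinates with no false
positives, and exactly the 10 planted differential circRNAs are significant
(Fisher P < 0.05), 5 up- and 5 down-regulated in RE. `demo_out/` contains the
QC table, the call table with origins and host genes, count/FPKM matrices,
the interval report, the differential table, enrichment results, the sponge
network and a per-criterion rejection log.

The same machinery is available as a library:

```python
from capricirc import fold_change
log2fc, fold, spec = fold_change(138.64, 9.02)   # PE mean, RE mean
# -> log2fc ≈ -3.94, fold ≈ 15.37, co_expressed
```

which reproduces, for instance, the published 15.37-fold decrease of the top
PE circRNA from its printed group means.

## Command-line interface

`capricirc {simulate, call, enrich, report, demo}` — see `--help` on each.
Exit codes: 0 success, 2 configuration error, 3 stage failure.
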