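"""Synthetic data generator: toy genomes, planted circRNAs, junction reads.

The generator emulates the statistical structure a back-splice analysis
assumes: multi-exon genes with canonical GT..AG introns on both strands,
circRNAs arising from exons (spanning whole exon runs), from single introns
(ciRNAs) and from intergenic space, and single-end junction-spanning reads
whose per-sample counts are Poisson around a planted abundance.  Everything
is seeded and byte-reproducible.

Default parameters describe the study conditions the downstream analysis is
tested under: a 2 conditions x 2 replicates design (PE1, PE2, RE1, RE2),
100-nt reads at constant Q30, 50 planted circRNAs of which 10 are 8-fold
differential between conditions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import revcomp
from .genome import AnnotatedGenome, Exon, Gene, intergenic_gaps

ILLUMINA_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

#: condition x replicate design of the sequenced samples
DEFAULT_DESIGN: Tuple[Tuple[str, str], ...] = (
    ("PE1", "PE"),
    ("PE2", "PE"),
    ("RE1", "RE"),
    ("RE2", "RE"),
)


# =========================================================================
# parameter blocks
# =========================================================================
@dataclass
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 120_000
    n_genes: int = 24
    exons_per_gene: Tuple[int, int] = (4, 6)
    exon_length: Tuple[int, int] = (150, 300)
    intron_length: Tuple[int, int] = (300, 800)
    gc_fraction: float = 0.42
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chrom_length, self.n_genes) < 1:
            raise ValueError("counts must be >= 1")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be positive and ordered")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0,1]")


@dataclass
class AbundanceSpec:
    """How planted circRNAs are expressed across the two conditions.

    `base_range` is the per-sample expected junction-read count (uniform draw)
    for non-differential circRNAs, identical in both conditions.
    `n_differential` circRNAs instead get `diff_low` in one condition and
    `diff_low * diff_fold` in the other, alternating direction.
    """

    base_range: Tuple[float, float] = (8.0, 20.0)
    n_differential: int = 10
    diff_fold: float = 8.0
    diff_low: float = 4.0
    conditions: Tuple[str, str] = ("PE", "RE")


@dataclass
class TruthCircRNA:
    chrom: str
    start: int  # 0-based half-open junction span
    end: int
    strand: str
    origin: str  # exonic | intronic | intergenic
    host_gene: Optional[str]
    abundance: Dict[str, float]  # condition -> expected junction reads/sample

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("truth circRNA needs start < end")

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def is_differential(self) -> bool:
        vals = list(self.abundance.values())
        return max(vals) != min(vals)


@dataclass
class ReadSimParams:
    read_length: int = 100
    n_linear_reads: int = 20_000
    mismatch_rate: float = 0.001
    constant_quality: int = 30
    adapter_contamination_rate: float = 0.01
    adapter: str = ILLUMINA_ADAPTER
    min_anchor: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read_length must be >= 2 x anchor length")
        for r in (self.mismatch_rate, self.adapter_contamination_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")


# =========================================================================
# genome generation
# =========================================================================
def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def generate_genome(spec: SyntheticGenomeSpec) -> AnnotatedGenome:
    """Build a toy genome with non-overlapping multi-exon genes.

    Every intron carries the canonical splice signal on the gene strand:
    GT at the donor, AG at the acceptor (genomically CT..AC for minus-strand
    genes).  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    sequences = {
        c: list(_random_sequence(rng, spec.chrom_length, spec.gc_fraction))
        for c in chrom_names
    }

    # round-robin genes across chromosomes
    per_chrom: Dict[str, int] = {c: 0 for c in chrom_names}
    for i in range(spec.n_genes):
        per_chrom[chrom_names[i % len(chrom_names)]] += 1

    genes: List[Gene] = []
    gene_no = 0
    min_gap = 200  # room for intergenic circRNAs and clean gene separation
    for chrom in chrom_names:
        n_here = per_chrom[chrom]
        if n_here == 0:
            continue
        structures = []
        for _ in range(n_here):
            n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
            ex_lens = rng.integers(
                spec.exon_length[0], spec.exon_length[1] + 1, size=n_ex
            )
            in_lens = rng.integers(
                spec.intron_length[0], spec.intron_length[1] + 1, size=n_ex - 1
            )
            structures.append((ex_lens.tolist(), in_lens.tolist()))
        total_span = sum(sum(e) + sum(i) for e, i in structures)
        slack = spec.chrom_length - total_span - (n_here + 1) * min_gap
        if slack < 0:
            raise ValueError(
                f"chromosome length {spec.chrom_length} too short for "
                f"{n_here} genes (need {total_span + (n_here + 1) * min_gap})"
            )
        # random extra gaps on top of the minimum
        extra = rng.multinomial(slack, np.ones(n_here + 1) / (n_here + 1))
        cursor = 0
        for gi, (ex_lens, in_lens) in enumerate(structures):
            cursor += min_gap + int(extra[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for k, el in enumerate(ex_lens):
                exons.append(Exon(pos, pos + el))
                pos += el
                if k < len(in_lens):
                    pos += in_lens[k]
            gene_no += 1
            genes.append(Gene(f"gene{gene_no:03d}", chrom, strand, exons))
            cursor = pos

    genome = AnnotatedGenome({c: "".join(s) for c, s in sequences.items()}, genes)

    # stamp splice signals onto every intron
    for g in genome.genes:
        for (istart, iend) in g.introns:
            if g.strand == "+":
                genome.patch(g.chrom, istart, "GT")
                genome.patch(g.chrom, iend - 2, "AG")
            else:
                genome.patch(g.chrom, istart, "CT")
                genome.patch(g.chrom, iend - 2, "AC")
    return genome


# =========================================================================
# circRNA planting
# =========================================================================
def _backsplice_signal_patches(
    strand: str, start: int, end: int
) -> List[Tuple[int, str]]:
    """Genomic dinucleotide patches that make span [start,end) look
    back-splice competent: acceptor preceded by AG, donor followed by GT on
    the junction strand."""
    if strand == "+":
        return [(start - 2, "AG"), (end, "GT")]
    return [(start - 2, "AC"), (end, "CT")]


def plant_circrnas(
    genome: AnnotatedGenome,
    n_exonic: int,
    n_intronic: int,
    n_intergenic: int,
    abundances: Optional[AbundanceSpec] = None,
    seed: int = 0,
) -> List[TruthCircRNA]:
    """Plant a ground-truth circRNA set on a generated genome.

    Exonic circRNAs span whole runs of internal exons of one gene, so their
    junction ends coincide with annotated exon boundaries and the flanking
    introns supply the GT/AG signals; a gene may host several.  Intronic
    circRNAs (ciRNAs) sit strictly inside one intron and intergenic ones in
    gene deserts; for those two classes the splice signals are patched into
    the genome just outside the span.
    """
    abund = abundances or AbundanceSpec()
    rng = np.random.default_rng(seed)

    # --- exonic: all internal exon runs, sampled without replacement
    runs = []
    for g in genome.genes:
        n = len(g.exons)
        for i in range(1, n - 1):
            for j in range(i, n - 1):
                runs.append((g, i, j))
    if n_exonic > len(runs):
        raise ValueError(
            f"cannot place {n_exonic} exonic circRNAs: only {len(runs)} "
            "internal exon runs available"
        )
    chosen = [runs[i] for i in rng.choice(len(runs), size=n_exonic, replace=False)]

    truths: List[TruthCircRNA] = []
    for g, i, j in chosen:
        truths.append(
            TruthCircRNA(
                g.chrom, g.exons[i].start, g.exons[j].end, g.strand,
                "exonic", g.gene_id, {},
            )
        )

    # --- intronic (ciRNA): one per intron, span strictly inside
    introns = []
    for g in genome.genes:
        for (s, e) in g.introns:
            if e - s >= 160 + 8:  # span >= 160 plus signal margin
                introns.append((g, s, e))
    if n_intronic > len(introns):
        raise ValueError("not enough introns for requested intronic circRNAs")
    picked = [introns[i] for i in rng.choice(len(introns), size=n_intronic, replace=False)]
    for g, istart, iend in picked:
        max_span = (iend - 4) - (istart + 4)
        span = int(rng.integers(160, max_span + 1)) if max_span > 160 else max_span
        s = int(rng.integers(istart + 4, iend - 4 - span + 1))
        e = s + span
        for pos, dinuc in _backsplice_signal_patches(g.strand, s, e):
            genome.patch(g.chrom, pos, dinuc)
        truths.append(
            TruthCircRNA(g.chrom, s, e, g.strand, "intronic", g.gene_id, {})
        )

    # --- intergenic: one per gap
    gaps = [
        gap for gap in intergenic_gaps(genome, min_length=160 + 20) if gap[2] - gap[1] >= 180
    ]
    if n_intergenic > len(gaps):
        raise ValueError("not enough intergenic space for requested circRNAs")
    picked_gaps = [gaps[i] for i in rng.choice(len(gaps), size=n_intergenic, replace=False)]
    for chrom, gstart, gend in picked_gaps:
        avail = gend - gstart - 8
        span = int(rng.integers(160, min(400, avail) + 1))
        s = int(rng.integers(gstart + 4, gend - 4 - span + 1))
        e = s + span
        strand = "+" if rng.random() < 0.5 else "-"
        for pos, dinuc in _backsplice_signal_patches(strand, s, e):
            genome.patch(chrom, pos, dinuc)
        truths.append(TruthCircRNA(chrom, s, e, strand, "intergenic", None, {}))

    # --- abundances: which circRNAs are differential, and their levels
    order = rng.permutation(len(truths))
    n_diff = min(abund.n_differential, len(truths))
    cond_a, cond_b = abund.conditions
    for rank, idx in enumerate(order):
        t = truths[idx]
        if rank < n_diff:
            lo, hi = abund.diff_low, abund.diff_low * abund.diff_fold
            if rank % 2 == 0:
                t.abundance = {cond_a: lo, cond_b: hi}  # up in B
            else:
                t.abundance = {cond_a: hi, cond_b: lo}  # down in B
        else:
            lam = float(rng.uniform(*abund.base_range))
            t.abundance = {cond_a: lam, cond_b: lam}

    truths.sort(key=lambda t: (t.chrom, t.start, t.end))
    return truths


# =========================================================================
# read simulation
# =========================================================================
def circle_sense_blocks(
    genome: AnnotatedGenome, circ: TruthCircRNA
) -> List[Tuple[int, int]]:
    """Genomic blocks of the circle, in sense (5'->3') order on its strand.

    Exonic circles are spliced (the exons of the host gene inside the span);
    intronic/intergenic circles are the plain genomic span.
    """
    if circ.origin == "exonic" and circ.host_gene is not None:
        gene = genome.gene(circ.host_gene)
        blocks = [
            (e.start, e.end)
            for e in gene.exons
            if e.start >= circ.start and e.end <= circ.end
        ]
        if circ.strand == "-":
            blocks = blocks[::-1]
        return blocks
    return [(circ.start, circ.end)]


def circle_sense_sequence(genome: AnnotatedGenome, circ: TruthCircRNA) -> str:
    parts = []
    for (s, e) in circle_sense_blocks(genome, circ):
        seq = genome.fetch(circ.chrom, s, e)
        parts.append(revcomp(seq) if circ.strand == "-" else seq)
    return "".join(parts)


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


@dataclass
class ReadSimResult:
    reads: Dict[str, List[Tuple[str, str]]]  # sample -> [(read_id, seq)]
    truth_counts: pd.DataFrame  # truth index x sample, realized junction reads
    fastq_paths: Dict[str, str] = field(default_factory=dict)
    quality_char: str = "?"  # Phred+33 for Q30


def simulate_reads(
    genome: AnnotatedGenome,
    truth: Sequence[TruthCircRNA],
    params: ReadSimParams,
    design: Sequence[Tuple[str, str]] = DEFAULT_DESIGN,
    outdir: Optional[str] = None,
) -> ReadSimResult:
    """Emit junction-spanning and linear background reads per sample.

    Junction reads per circRNA and sample are Poisson around the planted
    abundance for that sample's condition; each covers the back-splice point
    with at least `min_anchor` bases on both sides and never crosses an
    internal splice boundary of the circle (terminal-block geometry), so a
    two-segment genomic split mapper can place it exactly.  Adapter
    contamination is applied to linear reads only, keeping the realized
    junction-count table exact.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L, anchor = params.read_length, params.min_anchor
    qual_char = chr(params.constant_quality + 33)

    sense = {id(t): circle_sense_sequence(genome, t) for t in truth}
    blocks = {id(t): circle_sense_blocks(genome, t) for t in truth}

    reads: Dict[str, List[Tuple[str, str]]] = {}
    counts = np.zeros((len(truth), len(design)), dtype=int)

    for si, (sample, condition) in enumerate(design):
        out: List[Tuple[str, str]] = []
        serial = 0
        # ---- junction reads
        for ti, t in enumerate(truth):
            lam = t.abundance.get(condition, 0.0)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            seq = sense[id(t)]
            blk = blocks[id(t)]
            first_len = blk[0][1] - blk[0][0]
            last_len = blk[-1][1] - blk[-1][0]
            k_lo = max(anchor, L - first_len)
            k_hi = min(L - anchor, last_len, len(seq))
            if k_lo > k_hi:
                raise ValueError(
                    "read_length too large for circle terminal blocks"
                )
            emitted = 0
            for _ in range(n):
                k = int(rng.integers(k_lo, k_hi + 1))
                r = seq[len(seq) - k :] + seq[: L - k]
                if len(r) < L:  # circle shorter than a read; skip
                    continue
                r = _mutate(r, rng, params.mismatch_rate)
                serial += 1
                out.append((f"{sample}:junc:{serial}", r))
                emitted += 1
            counts[ti, si] = emitted
        # ---- linear background reads from transcripts
        transcripts = [
            g.spliced_sequence(genome)
            for g in genome.genes
        ]
        transcripts = [t for t in transcripts if len(t) >= L]
        for _ in range(params.n_linear_reads):
            tseq = transcripts[int(rng.integers(len(transcripts)))]
            pos = int(rng.integers(0, len(tseq) - L + 1))
            r = _mutate(tseq[pos : pos + L], rng, params.mismatch_rate)
            if rng.random() < params.adapter_contamination_rate:
                cut = int(rng.integers(L // 2, L - 12 + 1))
                r = r[:cut] + params.adapter[: L - cut]
            serial += 1
            out.append((f"{sample}:lin:{serial}", r))
        reads[sample] = out

    truth_counts = pd.DataFrame(
        counts,
        index=[f"{t.chrom}:{t.start}-{t.end}({t.strand})" for t in truth],
        columns=[s for s, _ in design],
    )
    result = ReadSimResult(reads, truth_counts, quality_char=qual_char)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for sample, rs in reads.items():
            path = os.path.join(outdir, f"{sample}.fastq")
            with open(path, "w") as fh:
                for rid, seq in rs:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")
            result.fastq_paths[sample] = path
        truth_counts.to_csv(
            os.path.join(outdir, "truth_counts.tsv"), sep="\t", index_label="circRNA"
        )
    return result


# =========================================================================
# truth set I/O
# =========================================================================
TRUTH_COLUMNS = ["chrom", "start", "end", "strand", "origin", "host_gene", "abundance"]


def write_truth_set(truth: Sequence[TruthCircRNA], path: str) -> None:
    """BED-like TSV; coordinates are written 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            ab = ",".join(f"{c}={v:g}" for c, v in sorted(t.abundance.items()))
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start + 1),
                        str(t.end),
                        t.strand,
                        t.origin,
                        t.host_gene or ".",
                        ab or ".",
                    ]
                )
                + "\n"
            )


def read_truth_set(path: str) -> List[TruthCircRNA]:
    out: List[TruthCircRNA] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth-set header: {header}")
        for line in fh:
            chrom, s, e, strand, origin, host, ab = line.rstrip("\n").split("\t")
            abundance = {}
            if ab != ".":
                for item in ab.split(","):
                    c, v = item.split("=")
                    abundance[c] = float(v)
            out.append(
                TruthCircRNA(
                    chrom, int(s) - 1, int(e), strand, origin,
                    None if host == "." else host, abundance,
                )
            )
    return out


# =========================================================================
# annotation-side synthetic inputs (term maps, miRNAs)
# =========================================================================
def synthesize_term_map(
    genes: Sequence[str],
    n_terms: int = 30,
    genes_per_term: Tuple[int, int] = (3, 12),
    seed: int = 0,
    namespace_cycle: Tuple[str, ...] = ("biological_process", "molecular_function", "cellular_component"),
) -> Tuple[Dict[str, set], Dict[str, str], Dict[str, str]]:
    """Random term -> gene-set map over the given gene universe.

    Returns (term_genes, term_names, term_namespaces)."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    term_genes: Dict[str, set] = {}
    names: Dict[str, str] = {}
    namespaces: Dict[str, str] = {}
    for i in range(n_terms):
        size = int(rng.integers(genes_per_term[0], min(genes_per_term[1], len(genes)) + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        tid = f"TERM:{i + 1:04d}"
        term_genes[tid] = {genes[j] for j in members}
        names[tid] = f"synthetic term {i + 1}"
        namespaces[tid] = namespace_cycle[i % len(namespace_cycle)]
    return term_genes, names, namespaces


def synthesize_mirnas(n: int = 20, length: int = 22, seed: int = 0) -> List[Tuple[str, str]]:
    """Random miRNA sequences (RNA alphabet), as (id, sequence) pairs."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGU"), size=length))
        out.append((f"syn-miR-{i + 1}", seq))
    return out


# =========================================================================
# the default end-to-end scenario
# =========================================================================
@dataclass
class Scenario:
    genome: AnnotatedGenome
    truth: List[TruthCircRNA]
    sim: ReadSimResult
    design: Tuple[Tuple[str, str], ...]


def default_scenario(
    seed: int = 0,
    outdir: Optional[str] = None,
    n_exonic: int = 30,
    n_intronic: int = 10,
    n_intergenic: int = 10,
    genome_spec: Optional[SyntheticGenomeSpec] = None,
    read_params: Optional[ReadSimParams] = None,
) -> Scenario:
    """The standard study-scale scenario: 50 planted circRNAs, 2x2 design,
    10 circRNAs 8-fold differential between PE and RE."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    gspec = genome_spec or SyntheticGenomeSpec(seed=int(seeds[0]))
    genome = generate_genome(gspec)
    truth = plant_circrnas(
        genome, n_exonic, n_intronic, n_intergenic,
        AbundanceSpec(), seed=int(seeds[1]),
    )
    params = read_params or ReadSimParams(seed=int(seeds[2]))
    params.seed = int(seeds[2])
    sim = simulate_reads(genome, truth, params, DEFAULT_DESIGN, outdir=outdir)
    if outdir is not None:
        genome.write(
            os.path.join(outdir, "genome.fa"), os.path.join(outdir, "genome.gtf")
        )
        write_truth_set(truth, os.path.join(outdir, "truth.tsv"))
    return Scenario(genome, truth, sim, DEFAULT_DESIGN)
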