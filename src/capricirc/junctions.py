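"""Read QC, desk-scale split-read mapping, and back-splice junction calling.

A circRNA announces itself in RNA-seq as a read that maps in two segments on
the same chromosome in *noncolinear* order: the second part of the read lands
upstream of the first, because the read crosses the covalent joint between a
downstream splice donor and an upstream splice acceptor.  This module finds
such reads on small genomes by exact terminal-anchor lookup plus extension,
then calls junctions under four acceptance criteria:

  1. canonical splice signal: GT immediately 3' of the donor and AG
     immediately 5' of the acceptor on the junction strand;
  2. at most `max_mismatches` mismatches per supporting read;
  3. at least `min_junction_reads` supporting reads;
  4. both ends on the same chromosome, no more than `max_span` apart.

Every rejected candidate is logged with exactly which criteria failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from ._util import percent, revcomp
from .genome import AnnotatedGenome, Gene

logger = logging.getLogger(__name__)

_AMBIGUOUS = ("*", -1)  # sentinel for k-mers seen at more than one locus


# =========================================================================
# read filtering
# =========================================================================
@dataclass
class ReadFilterPolicy:
    adapter_sequences: Tuple[str, ...] = ("AGATCGGAAGAGCACACGTCTGAACTCCAGTCA",)
    max_n_fraction: float = 0.05
    min_q: int = 20
    max_lowq_fraction: float = 0.2
    adapter_min_prefix: int = 12

    def __post_init__(self) -> None:
        for p in (self.max_n_fraction, self.max_lowq_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must be in [0,1]")


@dataclass
class FilterStats:
    raw_reads: int
    valid_reads: int
    n_adapter: int
    n_high_n: int
    n_low_quality: int

    @property
    def valid_ratio_pct(self) -> float:
        return percent(self.valid_reads, self.raw_reads) if self.raw_reads else 0.0


def _iter_fastq(path: str):
    """Yield (id, seq, quals) from a Phred+33 FASTQ, with line-numbered errors."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            lineno += 3
            if not plus.startswith("+") or len(qual) != len(seq):
                raise ValueError(f"{path}:{lineno}: malformed FASTQ record")
            yield header[1:].split()[0], seq, qual


def filter_reads(
    fastq: Union[str, Iterable[Tuple[str, str, str]]],
    policy: Optional[ReadFilterPolicy] = None,
    fastq_out: Optional[str] = None,
) -> Tuple[List[Tuple[str, str]], FilterStats]:
    """Drop adapter-contaminated, N-rich and low-quality reads.

    A read is removed iff it contains a >= `adapter_min_prefix`-nt prefix of
    any adapter as an exact substring, its N fraction exceeds
    `max_n_fraction`, or more than `max_lowq_fraction` of its bases are below
    `min_q`.  Returns the kept (id, seq) pairs plus QC counts; optionally
    writes the clean FASTQ.
    """
    policy = policy or ReadFilterPolicy()
    records = _iter_fastq(fastq) if isinstance(fastq, str) else fastq
    probes = [a[: policy.adapter_min_prefix] for a in policy.adapter_sequences]

    kept: List[Tuple[str, str]] = []
    kept_q: List[str] = []
    raw = n_adapter = n_high_n = n_lowq = 0
    for rid, seq, qual in records:
        raw += 1
        s = seq.upper()
        if any(p and p in s for p in probes):
            n_adapter += 1
            continue
        if s.count("N") > policy.max_n_fraction * len(s):
            n_high_n += 1
            continue
        low = sum(1 for c in qual if ord(c) - 33 < policy.min_q)
        if low > policy.max_lowq_fraction * len(qual):
            n_lowq += 1
            continue
        kept.append((rid, seq))
        kept_q.append(qual)

    if fastq_out is not None:
        with open(fastq_out, "w") as fh:
            for (rid, seq), qual in zip(kept, kept_q):
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    stats = FilterStats(raw, len(kept), n_adapter, n_high_n, n_lowq)
    return kept, stats


# =========================================================================
# split-read detection
# =========================================================================
@dataclass
class ChimericAlignment:
    """One read's two-segment mapping; the back-splice evidence unit.

    `seg_a` is where the first part of the read (in mapping orientation)
    lands, `seg_b` the second.  `colinear` is False iff seg_b maps upstream
    of seg_a on the same chromosome -- back-spliced ordering.
    """

    read_id: str
    chrom_a: str
    chrom_b: str
    strand: str  # orientation in which the read matched the forward genome
    seg_a: Tuple[int, int]
    seg_b: Tuple[int, int]
    mismatches: int
    colinear: bool
    sample: str = ""

    @property
    def acceptor(self) -> int:
        return self.seg_b[0]

    @property
    def donor(self) -> int:
        return self.seg_a[1]


@dataclass
class DetectionResult:
    chimeras: List[ChimericAlignment]
    n_reads: int = 0
    n_colinear: int = 0
    n_ambiguous: int = 0
    n_unplaced: int = 0
    colinear_positions: List[Tuple[str, int]] = field(default_factory=list)

    @property
    def n_mapped(self) -> int:
        """Placed fragments: colinear plus split (library-size denominator)."""
        return self.n_colinear + len(self.chimeras)


def build_anchor_index(genome: AnnotatedGenome, k: int) -> Dict[str, Tuple[str, int]]:
    """Exact k-mer -> unique locus map; repeated k-mers map to a sentinel."""
    cache = getattr(genome, "_anchor_index_cache", None)
    if cache is not None and cache[0] == k:
        return cache[1]
    idx: Dict[str, Tuple[str, int]] = {}
    for chrom, seq in genome.sequences.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer in idx:
                idx[kmer] = _AMBIGUOUS
            else:
                idx[kmer] = (chrom, i)
    genome._anchor_index_cache = (k, idx)  # type: ignore[attr-defined]
    return idx


def _hamming_flags(a: str, b: str) -> List[int]:
    return [0 if x == y else 1 for x, y in zip(a, b)]


def _has_splice_signal(ref: str, acceptor: int, donor: int) -> bool:
    """Canonical back-splice signal around span [acceptor, donor) on either
    strand: GT..AG forward, genomic AC..CT for the minus strand."""
    if acceptor < 2 or donor + 2 > len(ref):
        return False
    plus = ref[donor : donor + 2] == "GT" and ref[acceptor - 2 : acceptor] == "AG"
    minus = ref[acceptor - 2 : acceptor] == "AC" and ref[donor : donor + 2] == "CT"
    return plus or minus


def _place_oriented(
    seq: str,
    genome: AnnotatedGenome,
    index: Dict[str, Tuple[str, int]],
    k: int,
):
    """Try to place one read orientation.

    Returns ('colinear', (chrom, pos, mismatches)) | ('chimera', payload) |
    ('ambiguous', None) | (None, None).
    payload = (chrom, seg_a, seg_b, mismatches)
    """
    L = len(seq)
    h1 = index.get(seq[:k])
    h2 = index.get(seq[-k:])
    if h1 is _AMBIGUOUS or h2 is _AMBIGUOUS:
        return "ambiguous", None
    if h1 is not None:
        c1, p1 = h1
        ref = genome.sequences[c1]
        if p1 + L <= len(ref) and ref[p1 : p1 + L] == seq:
            return "colinear", (c1, p1, 0)
    if h1 is None or h2 is None:
        return None, None
    c1, p1 = h1
    c2, p2 = h2
    if c1 != c2:
        return None, None
    ref = genome.sequences[c1]
    if p2 + k - L == p1:
        # single contiguous placement with interior mismatches
        mism = sum(_hamming_flags(seq, ref[p1 : p1 + L]))
        return "colinear", (c1, p1, mism)
    # two segments: prefix at p1, suffix ending at p2+k; pick the split
    # point s in [k, L-k] minimising total mismatches
    ga = ref[p1 : p1 + L]
    gb_start = p2 + k - L
    pad = max(0, -gb_start)
    gb = ("N" * pad) + ref[max(0, gb_start) : p2 + k]
    if len(ga) < L:
        ga = ga + "N" * (L - len(ga))
    flags_a = _hamming_flags(seq, ga)
    flags_b = _hamming_flags(seq, gb)
    # prefix sums
    pre_a = [0]
    for f in flags_a:
        pre_a.append(pre_a[-1] + f)
    pre_b = [0]
    for f in flags_b:
        pre_b.append(pre_b[-1] + f)
    tot_b = pre_b[-1]
    s_lo = max(k, pad)
    s_hi = min(L - k, len(ref) - p1)
    if s_lo > s_hi:
        return None, None
    costs = {s: pre_a[s] + (tot_b - pre_b[s]) for s in range(s_lo, s_hi + 1)}
    best_m = min(costs.values())
    ties = [s for s in range(s_lo, s_hi + 1) if costs[s] == best_m]
    # Sequence identity around the joint makes the split point ambiguous and
    # would shift the junction off its splice signal; among equally good
    # splits, prefer one whose implied back-splice junction carries GT/AG.
    best_s = ties[0]
    if len(ties) > 1:
        for s in ties:
            donor = p1 + s
            acceptor = p2 + k - (L - s)
            if acceptor < donor and _has_splice_signal(ref, acceptor, donor):
                best_s = s
                break
    seg_a = (p1, p1 + best_s)
    seg_b = (p2 + k - (L - best_s), p2 + k)
    return "chimera", (c1, seg_a, seg_b, best_m)


def detect_split_reads(
    reads: Union[str, Sequence[Tuple[str, str]]],
    genome: AnnotatedGenome,
    anchor_len: int = 20,
    sample: str = "",
) -> DetectionResult:
    """Find chimeric (two-segment) placements for reads that fail colinear
    exact placement.

    `reads` is either a FASTQ path or (read_id, sequence) pairs.  Both read
    orientations are tried against the forward genome; reads whose terminal
    anchors hit more than one locus are discarded (unique-evidence counting).
    """
    if isinstance(reads, str):
        read_list = [(rid, seq) for rid, seq, _ in _iter_fastq(reads)]
    else:
        read_list = list(reads)
    if read_list and len(read_list[0][1]) < 2 * anchor_len:
        raise ValueError("reads shorter than two anchors")
    index = build_anchor_index(genome, anchor_len)

    result = DetectionResult([], n_reads=len(read_list))
    for rid, seq in read_list:
        seq = seq.upper()
        outcome = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            kind, payload = _place_oriented(oriented, genome, index, anchor_len)
            if kind == "colinear":
                result.n_colinear += 1
                result.colinear_positions.append((payload[0], payload[1]))
                outcome = "colinear"
                break
            if kind == "chimera":
                chrom, seg_a, seg_b, mism = payload
                result.chimeras.append(
                    ChimericAlignment(
                        rid, chrom, chrom, strand, seg_a, seg_b, mism,
                        colinear=seg_b[0] > seg_a[0], sample=sample,
                    )
                )
                outcome = "chimera"
                break
            if kind == "ambiguous":
                result.n_ambiguous += 1
                outcome = "ambiguous"
                break
        if outcome is None:
            result.n_unplaced += 1
    return result


# =========================================================================
# junction calling
# =========================================================================
@dataclass
class BacksplicePolicy:
    require_gt_ag: bool = True
    max_mismatches: int = 2
    min_junction_reads: int = 1
    max_span: int = 100_000
    same_chrom_only: bool = True

    def __post_init__(self) -> None:
        if min(self.max_mismatches, self.min_junction_reads, self.max_span) < 0:
            raise ValueError("policy thresholds must be >= 0")


@dataclass
class CircRNARecord:
    circ_id: str
    chrom: str
    start: int  # acceptor, 0-based
    end: int  # donor, half-open
    strand: str
    origin: Optional[str] = None
    host_gene: Optional[str] = None
    spliced_length: Optional[int] = None
    junction_reads: Dict[str, int] = field(default_factory=dict)
    fpkm: Dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def total_reads(self) -> int:
        return sum(self.junction_reads.values())


@dataclass
class RejectedCandidate:
    chrom: str
    start: int
    end: int
    n_reads: int
    failed: Tuple[str, ...]  # subset of {gt_ag, mismatch, min_reads, max_span, same_chrom}


def junction_strand(genome: AnnotatedGenome, chrom: str, start: int, end: int) -> Optional[str]:
    """Strand on which span [start,end) carries the canonical back-splice
    signal: GT after the donor and AG before the acceptor."""
    seq = genome.sequences[chrom]
    if start >= 2 and end + 2 <= len(seq):
        if seq[end : end + 2] == "GT" and seq[start - 2 : start] == "AG":
            return "+"
        if seq[start - 2 : start] == "AC" and seq[end : end + 2] == "CT":
            return "-"
    return None


def call_backsplice_junctions(
    chimeras: Union[Sequence[ChimericAlignment], Mapping[str, Sequence[ChimericAlignment]]],
    genome: AnnotatedGenome,
    policy: Optional[BacksplicePolicy] = None,
) -> Tuple[List[CircRNARecord], List[RejectedCandidate]]:
    """Group noncolinear chimeras into junction candidates and apply the four
    acceptance criteria.  Accepts a flat list or a {sample: chimeras} map.

    All criteria are evaluated for every candidate (no short-circuit), so the
    rejection log states exactly which failed.
    """
    policy = policy or BacksplicePolicy()
    if isinstance(chimeras, Mapping):
        tagged = [
            (sample, c) for sample, cs in chimeras.items() for c in cs
        ]
    else:
        tagged = [(c.sample or "S1", c) for c in chimeras]

    groups: Dict[Tuple[str, int, int], List[Tuple[str, ChimericAlignment]]] = {}
    cross_chrom: List[Tuple[str, ChimericAlignment]] = []
    for sample, c in tagged:
        if c.colinear:
            continue  # forward-spliced / rearranged-but-ordered: not back-splice
        if c.chrom_a != c.chrom_b:
            cross_chrom.append((sample, c))
            continue
        key = (c.chrom_a, c.acceptor, c.donor)
        groups.setdefault(key, []).append((sample, c))

    records: List[CircRNARecord] = []
    rejected: List[RejectedCandidate] = []

    if cross_chrom and policy.same_chrom_only:
        # aggregate cross-chromosome evidence into one logged rejection per pair
        by_pair: Dict[Tuple[str, str], int] = {}
        for _, c in cross_chrom:
            pair = tuple(sorted((c.chrom_a, c.chrom_b)))
            by_pair[pair] = by_pair.get(pair, 0) + 1
        for (ca, cb), n in sorted(by_pair.items()):
            rejected.append(RejectedCandidate(f"{ca}|{cb}", -1, -1, n, ("same_chrom",)))

    for (chrom, start, end), members in sorted(groups.items()):
        failed: List[str] = []
        strand = junction_strand(genome, chrom, start, end)
        if policy.require_gt_ag and strand is None:
            failed.append("gt_ag")
        if strand is None:
            # fall back to the orientation most reads mapped in
            plus = sum(1 for _, c in members if c.strand == "+")
            strand_eff = "+" if plus * 2 >= len(members) else "-"
        else:
            strand_eff = strand
        clean = [(s, c) for s, c in members if c.mismatches <= policy.max_mismatches]
        if len(clean) < policy.min_junction_reads:
            if len(clean) < len(members) and len(members) >= policy.min_junction_reads:
                failed.append("mismatch")  # exclusions caused the shortfall
            failed.append("min_reads")
        if end - start > policy.max_span:
            failed.append("max_span")
        if failed:
            rejected.append(
                RejectedCandidate(chrom, start, end, len(members), tuple(failed))
            )
            continue
        per_sample: Dict[str, int] = {}
        for s, _ in clean:
            per_sample[s] = per_sample.get(s, 0) + 1
        records.append(
            CircRNARecord(
                circ_id="",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand_eff,
                junction_reads=per_sample,
            )
        )

    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    for i, r in enumerate(records, start=1):
        r.circ_id = f"circRNA{i}"
    if rejected:
        logger.info("rejected %d junction candidates", len(rejected))
    return records, rejected


# =========================================================================
# origin classification
# =========================================================================
def classify_origin(circ: CircRNARecord, genome: AnnotatedGenome) -> CircRNARecord:
    """Assign origin class, host gene and spliced length.

    exonic: both junction ends coincide exactly with annotated exon
    boundaries of one gene (spliced length = sum of enclosed exon lengths);
    intronic (ciRNA): the span lies entirely within one intron;
    intergenic: the span overlaps no gene.  A span overlapping genes without
    an exact exon match is assigned to the gene with the largest overlap
    (ties by gene id), exonic if it touches any exon else intronic, with the
    span length as spliced length.
    """
    overlapping = genome.genes_overlapping(circ.chrom, circ.start, circ.end)
    if not overlapping:
        circ.origin = "intergenic"
        circ.host_gene = None
        circ.spliced_length = circ.span
        return circ

    exact: List[Gene] = []
    for g in overlapping:
        starts = {e.start for e in g.exons}
        ends = {e.end for e in g.exons}
        if circ.start in starts and circ.end in ends:
            exact.append(g)
    if exact:
        # prefer the gene on the junction strand, then lexicographic id
        exact.sort(key=lambda g: (g.strand != circ.strand, g.gene_id))
        host = exact[0]
        circ.origin = "exonic"
        circ.host_gene = host.gene_id
        circ.spliced_length = sum(
            len(e) for e in host.exons if e.start >= circ.start and e.end <= circ.end
        )
        return circ

    for g in overlapping:
        for (istart, iend) in g.introns:
            if istart <= circ.start and circ.end <= iend:
                circ.origin = "intronic"
                circ.host_gene = g.gene_id
                circ.spliced_length = circ.span
                return circ

    # ambiguous overlap: largest-overlap gene, ties by id; never an error
    def overlap(g: Gene) -> int:
        return min(circ.end, g.end) - max(circ.start, g.start)

    overlapping.sort(key=lambda g: (-overlap(g), g.gene_id))
    host = overlapping[0]
    touches_exon = any(
        e.start < circ.end and e.end > circ.start for e in host.exons
    )
    circ.origin = "exonic" if touches_exon else "intronic"
    circ.host_gene = host.gene_id
    circ.spliced_length = circ.span
    return circ


def classify_all(records: Sequence[CircRNARecord], genome: AnnotatedGenome) -> None:
    for r in records:
        classify_origin(r, genome)


# =========================================================================
# external chimeric-record ingest / export
# =========================================================================
def import_chimeric_records(path: str, dialect: str) -> List[ChimericAlignment]:
    """Ingest externally produced chimeric alignments.

    dialects:
      fusion-tsv: columns chrom, donor (1-based last base of the donor
        segment), acceptor (1-based first base), strand, n_reads; '#' lines
        are comments.  Each row expands to n_reads alignments with nominal
        20-bp segments.
      sam-supplementary: SAM records whose SA tag encodes the second segment.
    """
    if dialect == "fusion-tsv":
        out: List[ChimericAlignment] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns")
                chrom, donor, acceptor, strand, n = parts
                donor_end = int(donor)  # 1-based inclusive last base == half-open end
                acc0 = int(acceptor) - 1
                if donor_end < 0 or acc0 < 0:
                    raise ValueError(f"{path}:{lineno}: negative coordinate")
                for i in range(int(n)):
                    out.append(
                        ChimericAlignment(
                            read_id=f"{chrom}:{acceptor}-{donor}:{i + 1}",
                            chrom_a=chrom,
                            chrom_b=chrom,
                            strand=strand,
                            seg_a=(max(0, donor_end - 20), donor_end),
                            seg_b=(acc0, acc0 + 20),
                            mismatches=0,
                            colinear=acc0 > donor_end,
                        )
                    )
        return out
    if dialect == "sam-supplementary":
        return _import_sam_supplementary(path)
    raise ValueError(f"unknown chimeric dialect: {dialect}")


def _cigar_first_match_span(cigar) -> Tuple[int, int]:
    """(soft-clipped prefix, aligned reference length) from a cigartuples list."""
    ref = 0
    clip = 0
    seen_match = False
    for op, n in cigar:
        if op == 4 and not seen_match:  # leading S
            clip += n
        elif op in (0, 7, 8):  # M/=/X
            ref += n
            seen_match = True
    return clip, ref


def _import_sam_supplementary(path: str) -> List[ChimericAlignment]:
    import pysam

    out: List[ChimericAlignment] = []
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_supplementary or not rec.has_tag("SA"):
                continue
            sa = rec.get_tag("SA").rstrip(";").split(";")[0].split(",")
            sa_chrom, sa_pos, sa_strand = sa[0], int(sa[1]) - 1, sa[2]
            sa_cigar = sa[3]
            sa_nm = int(sa[5]) if len(sa) > 5 else 0
            # parse SA cigar reference length
            ref_len = 0
            num = ""
            for ch in sa_cigar:
                if ch.isdigit():
                    num += ch
                else:
                    if ch in "M=X":
                        ref_len += int(num)
                    num = ""
            seg_a = (rec.reference_start, rec.reference_end)
            seg_b = (sa_pos, sa_pos + ref_len)
            nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            strand = "-" if rec.is_reverse else "+"
            # order segments by read layout: leading soft clip on the primary
            # means the primary is the *second* read part
            clip, _ = _cigar_first_match_span(rec.cigartuples)
            if clip > 0:
                seg_a, seg_b = seg_b, seg_a
            out.append(
                ChimericAlignment(
                    read_id=rec.query_name,
                    chrom_a=rec.reference_name if clip == 0 else sa_chrom,
                    chrom_b=sa_chrom if clip == 0 else rec.reference_name,
                    strand=strand,
                    seg_a=seg_a,
                    seg_b=seg_b,
                    mismatches=nm + sa_nm,
                    colinear=seg_b[0] > seg_a[0],
                )
            )
    return out


def write_chimeric_sam(
    chimeras: Sequence[ChimericAlignment],
    path: str,
    genome: AnnotatedGenome,
) -> None:
    """Write chimeras as SAM: primary record carries the first segment and an
    SA tag pointing at the second.  Round-trips through
    import_chimeric_records(..., 'sam-supplementary')."""
    import pysam

    chroms = sorted(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome.sequences[c])} for c in chroms],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for c in chimeras:
            la = c.seg_a[1] - c.seg_a[0]
            lb = c.seg_b[1] - c.seg_b[0]
            a = pysam.AlignedSegment(out.header)
            a.query_name = c.read_id
            a.reference_id = chroms.index(c.chrom_a)
            a.reference_start = c.seg_a[0]
            a.cigarstring = f"{la}M{lb}S"
            a.flag = 16 if c.strand == "-" else 0
            seq_a = genome.fetch(c.chrom_a, *c.seg_a)
            seq_b = genome.fetch(c.chrom_b, *c.seg_b)
            a.query_sequence = seq_a + seq_b
            a.mapping_quality = 60
            sa = f"{c.chrom_b},{c.seg_b[0] + 1},{c.strand},{la}S{lb}M,60,0;"
            a.set_tag("SA", sa)
            a.set_tag("NM", c.mismatches)
            out.write(a)


def write_call_table(records: Sequence[CircRNARecord], path: str, samples: Sequence[str]) -> None:
    """circRNA call table, 1-based inclusive coordinates, per-sample counts."""
    with open(path, "w") as fh:
        cols = ["circ_id", "chrom", "start", "end", "strand", "origin",
                "host_gene", "spliced_length"] + [f"reads_{s}" for s in samples]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.circ_id, r.chrom, str(r.start + 1), str(r.end), r.strand,
                r.origin or ".", r.host_gene or ".",
                str(r.spliced_length if r.spliced_length is not None else "."),
            ] + [str(r.junction_reads.get(s, 0)) for s in samples]
            fh.write("\t".join(row) + "\n")
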