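"""End-to-end orchestration, QC summary tables, host-gene correlation and
small report utilities.

The pipeline runs simulate (optional) -> filter -> detect -> call ->
quantify -> differential test -> enrichment -> sponge network -> report.
Every stage's counters are first-class outputs; all printed percentages are
recomputable from the adjacent counts.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from ._util import percent
from . import synthetic
from .diffexp import (
    GroupDesign,
    classify_dec,
    differential_expression,
    format_dec_table,
    volcano_data,
)
from .enrich import AnnotationMap, enrich, significant, summarize_pathways, write_enrichment
from .evaluate import differential_sensitivity, evaluate_calls
from .genome import AnnotatedGenome
from .junctions import (
    BacksplicePolicy,
    ReadFilterPolicy,
    call_backsplice_junctions,
    classify_all,
    detect_split_reads,
    filter_reads,
    import_chimeric_records,
    write_call_table,
)
from .quantify import (
    ExpressionTable,
    IntervalBinning,
    bin_expression,
    build_expression_table,
    length_distribution,
    origin_distribution,
)
from .sponge import (
    MiRNA,
    build_network,
    export_network,
    load_mirnas_fasta,
    scan_seed_sites,
    score_duplex,
)
from .synthetic import circle_sense_sequence

logger = logging.getLogger(__name__)


# =========================================================================
# small report ops
# =========================================================================
def qpcr_relative_expression(delta_delta_ct: float) -> float:
    """Relative expression N = 2^(-ddCt)."""
    return 2.0 ** (-delta_delta_ct)


def correlate_host(
    circ_values: Sequence[float], host_values: Sequence[float]
) -> Tuple[float, float]:
    """Pearson r and two-sided p between circRNA and host-gene expression."""
    x = np.asarray(circ_values, dtype=float)
    y = np.asarray(host_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def qc_summary(stage_counts: pd.DataFrame) -> pd.DataFrame:
    """Add recomputable percentage columns to a per-sample stage-count table.

    Requires columns raw_reads and valid_reads; candidate_reads is optional.
    """
    df = stage_counts.copy()
    if (df["raw_reads"] <= 0).any():
        raise ValueError("raw read count must be positive")
    df["valid_ratio_pct"] = [
        percent(v, r) for v, r in zip(df["valid_reads"], df["raw_reads"])
    ]
    if "candidate_reads" in df.columns:
        df["candidate_pct"] = [
            percent(c, v) for c, v in zip(df["candidate_reads"], df["valid_reads"])
        ]
    return df


# =========================================================================
# configuration
# =========================================================================
class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "capricirc_out"
    seed: int = 0
    simulate: bool = True
    # external-input mode
    genome_fasta: Optional[str] = None
    genome_gtf: Optional[str] = None
    reads: Dict[str, str] = field(default_factory=dict)  # sample -> fastq
    chimeras_path: Optional[str] = None
    chimeras_dialect: str = "fusion-tsv"
    mirna_fasta: Optional[str] = None
    term_map: Optional[str] = None
    term_meta: Optional[str] = None
    # policies
    filter_policy: ReadFilterPolicy = field(default_factory=ReadFilterPolicy)
    backsplice_policy: BacksplicePolicy = field(default_factory=BacksplicePolicy)
    binning: IntervalBinning = field(default_factory=IntervalBinning)
    design: GroupDesign = field(default_factory=GroupDesign)
    anchor_len: int = 20
    # synthetic-annotation sizes for simulate mode
    n_synthetic_mirnas: int = 20
    n_synthetic_terms: int = 30
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("outdir", "seed", "simulate", "genome_fasta", "genome_gtf",
                    "chimeras_path", "chimeras_dialect", "mirna_fasta",
                    "term_map", "term_meta", "anchor_len",
                    "n_synthetic_mirnas", "n_synthetic_terms", "log_level"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "reads" in raw:
            cfg.reads = dict(raw["reads"])
        for section, attr in (
            ("filter_policy", ReadFilterPolicy),
            ("backsplice_policy", BacksplicePolicy),
            ("binning", IntervalBinning),
        ):
            if section in raw:
                params = dict(raw[section])
                if section == "filter_policy" and "adapter_sequences" in params:
                    params["adapter_sequences"] = tuple(params["adapter_sequences"])
                if section == "binning":
                    for k in ("boundaries", "labels"):
                        if k in params:
                            params[k] = tuple(params[k])
                setattr(cfg, section, attr(**params))
        if "design" in raw:
            d = raw["design"]
            cfg.design = GroupDesign(
                group_a=d.get("group_a", "PE"),
                group_b=d.get("group_b", "RE"),
                sample_groups=dict(d.get("sample_groups", {})),
                alpha=d.get("alpha", 0.05),
                q_threshold=d.get("q_threshold", 0.01),
                use_q=d.get("use_q", False),
            )
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for label, path in [
                ("genome_fasta", self.genome_fasta),
                ("genome_gtf", self.genome_gtf),
            ]:
                if not path:
                    raise ConfigError(f"{label} is required when simulate is false")
                if not os.path.exists(path):
                    raise ConfigError(f"{label} does not exist: {path}")
            if not self.reads and not self.chimeras_path:
                raise ConfigError("need reads or a chimeric-record file")
            for s, p in self.reads.items():
                if not os.path.exists(p):
                    raise ConfigError(f"reads for {s} missing: {p}")
            if self.chimeras_path and not os.path.exists(self.chimeras_path):
                raise ConfigError(f"chimeras file missing: {self.chimeras_path}")
        for opt in (self.mirna_fasta, self.term_map, self.term_meta):
            if opt and not os.path.exists(opt):
                raise ConfigError(f"configured path missing: {opt}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# =========================================================================
# pipeline
# =========================================================================
@dataclass
class PipelineReport:
    qc: pd.DataFrame
    records: list
    rejected: list
    expression: ExpressionTable
    interval_report: pd.DataFrame
    length_fraction_over_1kb: float
    origin_fractions: Dict[str, float]
    dec_table: pd.DataFrame
    dec_summary: Dict[str, int]
    enrichment: list
    network_stats: Dict[str, float]
    host_correlation: Dict[str, Tuple[float, float]]
    truth_eval: Optional[Dict[str, float]] = None
    dec_eval: Optional[Dict[str, float]] = None
    config_hash: str = ""
    seed: int = 0


def _gene_read_counts(
    genome: AnnotatedGenome, positions: Sequence[Tuple[str, int]]
) -> Dict[str, int]:
    """Assign colinear read start positions to genes (by span containment)."""
    counts: Dict[str, int] = {}
    starts: Dict[str, List[int]] = {}
    spans: Dict[str, List[Tuple[int, int, str]]] = {}
    for chrom in genome.sequences:
        glist = genome.genes_on(chrom)
        starts[chrom] = [g.start for g in glist]
        spans[chrom] = [(g.start, g.end, g.gene_id) for g in glist]
    for chrom, pos in positions:
        arr = starts.get(chrom, [])
        i = bisect.bisect_right(arr, pos) - 1
        if i >= 0:
            s, e, gid = spans[chrom][i]
            if s <= pos < e:
                counts[gid] = counts.get(gid, 0) + 1
    return counts


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full analysis and write the report bundle to
    config.outdir.  Deterministic for a fixed config and seed."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    cfg_hash = config.config_hash()

    truth = None
    sim = None

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except (ConfigError, StageError):
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise StageError(name, exc) from exc
        return deco

    # ---- stage: inputs (simulate or load)
    if config.simulate:
        def _sim():
            return synthetic.default_scenario(seed=int(seeds[0]), outdir=config.outdir)
        scenario = _stage("simulate")(_sim)
        genome, truth, sim = scenario.genome, scenario.truth, scenario.sim
        design = config.design
        raw_reads = {s: sim.reads[s] for s, _ in scenario.design}
        qchar = sim.quality_char
        read_iters = {
            s: [(rid, seq, qchar * len(seq)) for rid, seq in rs]
            for s, rs in raw_reads.items()
        }
    else:
        def _load():
            return AnnotatedGenome.from_files(config.genome_fasta, config.genome_gtf)
        genome = _stage("load_genome")(_load)
        design = config.design
        read_iters = {s: p for s, p in config.reads.items()}

    # ---- stage: filter + detect per sample
    qc_rows = []
    chimeras_by_sample = {}
    library_sizes: Dict[str, int] = {}
    gene_counts_by_sample: Dict[str, Dict[str, int]] = {}
    for sample in read_iters:
        src = read_iters[sample]
        def _filter(src=src):
            return filter_reads(src, config.filter_policy)
        kept, fstats = _stage(f"filter[{sample}]")(_filter)
        def _detect(kept=kept, sample=sample):
            return detect_split_reads(kept, genome, config.anchor_len, sample=sample)
        det = _stage(f"detect[{sample}]")(_detect)
        chimeras_by_sample[sample] = det.chimeras
        library_sizes[sample] = det.n_mapped
        gene_counts_by_sample[sample] = _gene_read_counts(genome, det.colinear_positions)
        n_candidates = sum(1 for c in det.chimeras if not c.colinear)
        qc_rows.append(
            {
                "sample": sample,
                "raw_reads": fstats.raw_reads,
                "valid_reads": fstats.valid_reads,
                "candidate_reads": n_candidates,
                "mapped_fragments": det.n_mapped,
                "ambiguous_reads": det.n_ambiguous,
                "unplaced_reads": det.n_unplaced,
            }
        )

    # ---- stage: externally supplied chimeras
    if config.chimeras_path:
        def _imp():
            return import_chimeric_records(config.chimeras_path, config.chimeras_dialect)
        imported = _stage("import_chimeras")(_imp)
        for c in imported:
            chimeras_by_sample.setdefault(c.sample or "external", []).append(c)
            library_sizes.setdefault(c.sample or "external", 0)
            library_sizes[c.sample or "external"] += 1

    # ---- stage: junction calling + origin
    def _call():
        return call_backsplice_junctions(chimeras_by_sample, genome, config.backsplice_policy)
    records, rejected = _stage("call")(_call)
    classify_all(records, genome)

    # ---- stage: quantification
    def _quant():
        return build_expression_table(records, library_sizes)
    expression = _stage("quantify")(_quant)
    interval_report = bin_expression(expression, config.binning)
    _, frac_1kb = length_distribution(records)
    origins = origin_distribution(records)

    # ---- stage: differential expression
    def _diff():
        return differential_expression(expression, design)
    dec_table = _stage("difftest")(_diff)
    dec_summary = classify_dec(dec_table, design)

    # ---- stage: enrichment of DEC host genes
    def _enrich():
        host_by_circ = {r.circ_id: r.host_gene for r in records}
        universe = sorted({g for g in host_by_circ.values() if g})
        dec_ids = dec_table.index[dec_table["significant"]] if len(dec_table) else []
        study = sorted({host_by_circ[c] for c in dec_ids if host_by_circ.get(c)})
        if config.term_map:
            annot = AnnotationMap.from_tsv(config.term_map, config.term_meta, universe=universe)
        else:
            tg, names, ns = synthetic.synthesize_term_map(
                universe, n_terms=config.n_synthetic_terms, seed=int(seeds[1])
            )
            annot = AnnotationMap(tg, names, ns, set(universe))
        return enrich(study, annot) if study and annot.term_genes else []
    enr = _stage("enrich")(_enrich)

    # ---- stage: sponge network over DEC circRNAs
    def _sponge():
        if config.mirna_fasta:
            mirnas = load_mirnas_fasta(config.mirna_fasta)
        else:
            mirnas = [
                MiRNA(mid, seq)
                for mid, seq in synthetic.synthesize_mirnas(
                    n=config.n_synthetic_mirnas, seed=int(seeds[2])
                )
            ]
        dec_ids = set(dec_table.index[dec_table["significant"]]) if len(dec_table) else set()
        targets = [r for r in records if r.circ_id in dec_ids] or list(records)
        sites = []
        for r in targets:
            seq = _record_sense_sequence(genome, r)
            for m in mirnas:
                found = scan_seed_sites(r.circ_id, seq, m)
                for s in found:
                    score_duplex(s, m, seq)
                sites.extend(found)
        return build_network(sites)
    net = _stage("sponge")(_sponge)

    # ---- stage: circRNA / host-gene correlation per group
    host_corr: Dict[str, Tuple[float, float]] = {}
    for group in (design.group_a, design.group_b):
        samples = [s for s in design.samples_in(group) if s in expression.counts.columns]
        if not samples:
            continue
        xs, ys = [], []
        for r in records:
            if not r.host_gene:
                continue
            gene = genome.gene(r.host_gene)
            glen = sum(len(e) for e in gene.exons)
            circ_vals, host_vals = [], []
            for s in samples:
                circ_vals.append(expression.fpkm.at[r.circ_id, s])
                gc = gene_counts_by_sample.get(s, {}).get(r.host_gene, 0)
                host_vals.append(gc * 1e9 / (glen * max(library_sizes[s], 1)))
            xs.append(float(np.mean(circ_vals)))
            ys.append(float(np.mean(host_vals)))
        try:
            host_corr[group] = correlate_host(xs, ys)
        except ValueError:
            pass

    # ---- evaluation against truth (simulate mode only)
    truth_eval = dec_eval = None
    if truth is not None:
        truth_eval = evaluate_calls(records, truth)
        dec_eval = differential_sensitivity(dec_table, records, truth)

    qc = qc_summary(pd.DataFrame(qc_rows).set_index("sample"))

    report = PipelineReport(
        qc=qc, records=records, rejected=rejected, expression=expression,
        interval_report=interval_report, length_fraction_over_1kb=frac_1kb,
        origin_fractions=origins, dec_table=dec_table, dec_summary=dec_summary,
        enrichment=enr, network_stats=net.degree_stats(),
        host_correlation=host_corr, truth_eval=truth_eval, dec_eval=dec_eval,
        config_hash=cfg_hash, seed=config.seed,
    )
    _write_bundle(report, net, config)
    return report


def _record_sense_sequence(genome: AnnotatedGenome, record) -> str:
    """Sense sequence of a called circRNA: spliced exons for exonic calls,
    the genomic span otherwise."""
    from ._util import revcomp

    if record.origin == "exonic" and record.host_gene:
        gene = genome.gene(record.host_gene)
        blocks = [
            (e.start, e.end)
            for e in gene.exons
            if e.start >= record.start and e.end <= record.end
        ]
        if blocks:
            if record.strand == "-":
                blocks = blocks[::-1]
            parts = [
                revcomp(genome.fetch(record.chrom, s, e))
                if record.strand == "-"
                else genome.fetch(record.chrom, s, e)
                for s, e in blocks
            ]
            return "".join(parts)
    seq = genome.fetch(record.chrom, record.start, record.end)
    return revcomp(seq) if record.strand == "-" else seq


def _write_bundle(report: PipelineReport, net, config: RunConfig) -> None:
    out = config.outdir
    samples = list(report.expression.counts.columns)
    report.qc.to_csv(os.path.join(out, "qc_stats.tsv"), sep="\t")
    write_call_table(report.records, os.path.join(out, "circ_calls.tsv"), samples)
    report.expression.write(
        os.path.join(out, "junction_counts.tsv"), os.path.join(out, "fpkm.tsv")
    )
    report.interval_report.to_csv(os.path.join(out, "interval_report.tsv"), sep="\t")
    format_dec_table(report.dec_table).to_csv(os.path.join(out, "diffexp.tsv"), sep="\t")
    volcano_data(report.dec_table).to_csv(os.path.join(out, "volcano.tsv"), sep="\t")
    write_enrichment(report.enrichment, os.path.join(out, "enrichment.tsv"))
    summarize_pathways(report.enrichment).to_csv(
        os.path.join(out, "pathway_summary.tsv"), sep="\t", index=False
    )
    export_network(net, os.path.join(out, "network_edges.tsv"), "edge-list")
    export_network(net, os.path.join(out, "network.sif"), "sif")
    with open(os.path.join(out, "rejected_candidates.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tn_reads\tfailed_criteria\n")
        for r in report.rejected:
            fh.write(f"{r.chrom}\t{r.start + 1}\t{r.end}\t{r.n_reads}\t{','.join(r.failed)}\n")

    lines = [
        "capricirc run report",
        f"config_hash: {report.config_hash}",
        f"seed: {report.seed}",
        "",
        "== QC ==",
        report.qc.to_string(),
        "",
        f"circRNAs called: {len(report.records)}",
        f"host genes: {len({r.host_gene for r in report.records if r.host_gene})}",
        f"origin fractions: {report.origin_fractions}",
        f"fraction spliced length > 1 kb: {report.length_fraction_over_1kb:.3f}",
        "",
        "== differential expression ==",
        json.dumps(report.dec_summary, indent=1),
        "",
        "== enrichment ==",
        f"terms tested: {len(report.enrichment)}; significant (q<0.05): "
        f"{sum(1 for r in report.enrichment if r.q_value < 0.05)}",
        "",
        "== sponge network ==",
        json.dumps(report.network_stats, indent=1),
        "",
        "== host-gene correlation (Pearson) ==",
        json.dumps({k: [round(v[0], 4), v[1]] for k, v in report.host_correlation.items()}, indent=1),
    ]
    if report.truth_eval is not None:
        lines += [
            "",
            "== truth evaluation ==",
            json.dumps(report.truth_eval, indent=1),
            json.dumps(report.dec_eval, indent=1),
        ]
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
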