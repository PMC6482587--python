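"""Annotated genome container: sequences plus gene/exon/intron intervals.

All coordinates are 0-based, half-open internally.  Files (FASTA/GTF) use the
conventional 1-based, inclusive coordinates; conversion happens only at the
I/O boundary.  One transcript per gene: the model genomes used here carry a
single isoform, which is all the back-splice analysis needs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from ._util import revcomp


@dataclass(frozen=True)
class Exon:
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Exon]  # sorted by genomic start

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> List[Tuple[int, int]]:
        """Genomic intervals between consecutive exons."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    def spliced_sequence(self, genome: "AnnotatedGenome") -> str:
        """Transcript sequence 5'->3' on the gene strand."""
        parts = [genome.fetch(self.chrom, e.start, e.end) for e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class AnnotatedGenome:
    """Sequences plus gene annotation; the coordinate authority for all calls."""

    sequences: Dict[str, str]
    genes: List[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._genes_by_chrom: Dict[str, List[Gene]] = {}
        for g in self.genes:
            self._genes_by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self._genes_by_chrom.values():
            glist.sort(key=lambda g: g.start)

    # ------------------------------------------------------------------ access
    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(
                f"interval {chrom}:{start}-{end} outside chromosome (len {len(seq)})"
            )
        return seq[start:end]

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def genes_on(self, chrom: str) -> List[Gene]:
        return self._genes_by_chrom.get(chrom, [])

    def genes_overlapping(self, chrom: str, start: int, end: int) -> List[Gene]:
        return [
            g for g in self.genes_on(chrom) if g.start < end and g.end > start
        ]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def patch(self, chrom: str, pos: int, replacement: str) -> None:
        """Overwrite bases in place (used when planting splice signals)."""
        seq = self.sequences[chrom]
        if pos < 0 or pos + len(replacement) > len(seq):
            raise IndexError("patch outside chromosome")
        self.sequences[chrom] = seq[:pos] + replacement + seq[pos + len(replacement):]

    def reverse_complemented(self) -> "AnnotatedGenome":
        """Mirror image of the genome: every chromosome reverse-complemented,
        annotation coordinates flipped and strands swapped."""
        seqs = {c: revcomp(s) for c, s in self.sequences.items()}
        genes = []
        for g in self.genes:
            L = len(self.sequences[g.chrom])
            exons = [Exon(L - e.end, L - e.start) for e in g.exons]
            genes.append(
                Gene(g.gene_id, g.chrom, "-" if g.strand == "+" else "+", exons)
            )
        return AnnotatedGenome(seqs, genes)

    # -------------------------------------------------------------------- I/O
    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str, source: str = "capricirc") -> None:
        """GTF with gene/transcript/exon features, 1-based inclusive."""
        with open(path, "w") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                tid = f"{g.gene_id}.t1"
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                rows = [("gene", g.start, g.end), ("transcript", g.start, g.end)]
                rows += [("exon", e.start, e.end) for e in g.exons]
                for feat, s, e in rows:
                    fh.write(
                        "\t".join(
                            [
                                g.chrom,
                                source,
                                feat,
                                str(s + 1),
                                str(e),
                                ".",
                                g.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )

    def write(self, fasta_path: str, gtf_path: str) -> None:
        self.write_fasta(fasta_path)
        self.write_gtf(gtf_path)

    @classmethod
    def from_files(cls, fasta_path: str, gtf_path: str) -> "AnnotatedGenome":
        import gffutils
        from pyfaidx import Fasta

        fa = Fasta(fasta_path)
        sequences = {name: str(fa[name][:]) for name in fa.keys()}

        db = gffutils.create_db(
            gtf_path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes: List[Gene] = []
        for gfeat in db.features_of_type("gene"):
            gid = gfeat.attributes["gene_id"][0]
            exons = [
                Exon(e.start - 1, e.end)
                for e in db.children(gfeat, featuretype="exon")
            ]
            if not exons:  # gene with no exon rows: treat the span as one exon
                exons = [Exon(gfeat.start - 1, gfeat.end)]
            genes.append(Gene(gid, gfeat.seqid, gfeat.strand, exons))
        return cls(sequences, genes)


def intergenic_gaps(
    genome: AnnotatedGenome, min_length: int = 1
) -> List[Tuple[str, int, int]]:
    """Maximal intervals on each chromosome overlapping no gene."""
    gaps = []
    for chrom, seq in genome.sequences.items():
        cursor = 0
        for g in genome.genes_on(chrom):
            if g.start - cursor >= min_length:
                gaps.append((chrom, cursor, g.start))
            cursor = max(cursor, g.end)
        if len(seq) - cursor >= min_length:
            gaps.append((chrom, cursor, len(seq)))
    return gaps
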