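"""circRNA-miRNA sponge prediction and the ceRNA bipartite network.

A circRNA sponges a miRNA through miRNA response elements (MREs): stretches
complementary to the miRNA seed.  Sites are scanned on the *circularized*
sequence (the molecule is a covalent circle, so a site may span the
back-splice junction) using the canonical seed-match classes:

    6mer      perfect match to miRNA positions 2-7
    7mer-m8   positions 2-8
    7mer-A1   positions 2-7 plus an A opposite miRNA position 1
    8mer      positions 2-8 plus the A1 anchor

A transparent linear duplex score over the miRNA 3' region (+1 Watson-Crick,
+0.5 G:U wobble, -1 mismatch) can filter edges; by default every seed match
is kept.  Sequences are normalized to the DNA alphabet internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from ._util import dna_to_rna, revcomp, rna_to_dna

SITE_CLASS_RANK = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
MAX_SITE_LEN = 8

# Watson-Crick pairs (miRNA base, target DNA base) and G:U wobbles
_WC = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("U", "G")}


@dataclass(frozen=True)
class MiRNA:
    mirna_id: str
    sequence: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        seq = dna_to_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 18:
            raise ValueError(f"{self.mirna_id}: miRNA shorter than 18 nt")
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: invalid alphabet")

    @property
    def seed(self) -> str:
        """Positions 2-8, 5'->3' (RNA)."""
        return self.sequence[1:8]


@dataclass
class SeedSite:
    circ_id: str
    mirna_id: str
    site_class: str
    position: int  # 5'-most offset of the full site on the circle, 0-based
    spans_junction: bool
    duplex_score: float = 0.0


def load_mirnas_fasta(path: str) -> List[MiRNA]:
    from Bio import SeqIO

    return [MiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def circularize_sequence(seq: str, max_site_len: int = MAX_SITE_LEN) -> str:
    """Append the first max_site_len-1 bases so a linear scan sees every
    site of length <= max_site_len on the circle exactly once."""
    if not seq:
        raise ValueError("empty sequence")
    ext = max_site_len - 1
    if ext <= 0:
        return seq
    reps = -(-ext // len(seq))  # handle circles shorter than a site
    return seq + (seq * reps)[:ext]


def scan_seed_sites(
    circ_id: str,
    circ_seq: str,
    mirna: MiRNA,
    circular: bool = True,
) -> List[SeedSite]:
    """All seed-match sites of one miRNA on one circRNA sense sequence.

    The site is the reverse complement of the seed on the circle's sense
    strand; match starts are confined to the original sequence length so
    each circular site is reported once.
    """
    seq = rna_to_dna(circ_seq)
    if set(seq) - set("ACGTN"):
        raise ValueError(f"{circ_id}: invalid nucleotide alphabet")
    n = len(seq)
    scan = circularize_sequence(seq, MAX_SITE_LEN) if circular else seq
    mseq = mirna.sequence
    core6 = revcomp(rna_to_dna(mseq[1:7]))  # positions 2-7
    m8_target = revcomp(rna_to_dna(mseq[7]))  # complement of position 8
    sites: List[SeedSite] = []
    limit = n if circular else n - 6 + 1
    for p in range(max(0, limit)):
        if scan[p : p + 6] != core6:
            continue
        if circular:
            has_m8 = seq[(p - 1) % n] == m8_target
        else:
            has_m8 = p >= 1 and seq[p - 1] == m8_target
        if circular:
            has_a1 = scan[p + 6] == "A" if p + 6 < len(scan) else False
        else:
            has_a1 = p + 6 < n and seq[p + 6] == "A"
        if has_m8 and has_a1:
            cls = "8mer"
        elif has_m8:
            cls = "7mer-m8"
        elif has_a1:
            cls = "7mer-A1"
        else:
            cls = "6mer"
        site_start = (p - 1) % n if (has_m8 and circular) else (p - 1 if has_m8 else p)
        site_len = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[cls]
        spans = circular and (site_start + site_len > n or (has_m8 and p == 0))
        sites.append(
            SeedSite(circ_id, mirna.mirna_id, cls, site_start, spans)
        )
    return sites


def score_duplex(site: SeedSite, mirna: MiRNA, circ_seq: str) -> float:
    """Complementarity score of the miRNA 3' region (positions 9..end)
    against the target bases 5' of the seed match, antiparallel, ungapped:
    +1 Watson-Crick, +0.5 G:U wobble, -1 mismatch."""
    seq = rna_to_dna(circ_seq)
    n = len(seq)
    # 5'-most target base opposite miRNA position 8 (or 7): site.position;
    # the core (positions 2-7 match) starts one base 3' for m8 classes.
    core_start = site.position + 1 if site.site_class in ("8mer", "7mer-m8") else site.position
    score = 0.0
    for i, mbase in enumerate(mirna.sequence[8:]):
        t = seq[(core_start - 2 - i) % n]
        if (mbase, t) in _WC:
            score += 1.0
        elif (mbase, t) in _WOBBLE:
            score += 0.5
        else:
            score -= 1.0
    site.duplex_score = score
    return score


@dataclass
class InteractionEdge:
    circ_id: str
    mirna_id: str
    best_site: str
    site_count: int
    best_score: float


@dataclass
class CeRNANetwork:
    graph: nx.Graph

    @property
    def circ_nodes(self) -> List[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "circRNA"]

    @property
    def mirna_nodes(self) -> List[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "miRNA"]

    @property
    def edges(self) -> List[InteractionEdge]:
        return [
            InteractionEdge(
                d["circ_id"], d["mirna_id"], d["best_site"], d["site_count"], d["best_score"]
            )
            for _, _, d in self.graph.edges(data=True)
        ]

    def degree_stats(self) -> Dict[str, float]:
        mir_deg = [self.graph.degree(m) for m in self.mirna_nodes if self.graph.degree(m) > 0]
        circ_deg = [self.graph.degree(c) for c in self.circ_nodes if self.graph.degree(c) > 0]
        n_edges = self.graph.number_of_edges()
        return {
            "n_edges": float(n_edges),
            "n_circ": float(len(self.circ_nodes)),
            "n_mirna": float(len(self.mirna_nodes)),
            "mean_circ_per_mirna": (n_edges / len(mir_deg)) if mir_deg else 0.0,
            "mean_mirna_per_circ": (n_edges / len(circ_deg)) if circ_deg else 0.0,
        }


def build_network(
    sites: Sequence[SeedSite],
    dec_set: Optional[Iterable[str]] = None,
    duplex_threshold: Optional[float] = None,
) -> CeRNANetwork:
    """One edge per (circRNA, miRNA) pair with at least one retained site.

    `dec_set` restricts circRNA nodes to a subset (e.g. the differentially
    expressed ones).  `duplex_threshold` keeps only sites with duplex_score
    >= threshold; None keeps every seed match.
    """
    dec = set(dec_set) if dec_set is not None else None
    by_pair: Dict[Tuple[str, str], List[SeedSite]] = {}
    for s in sites:
        if dec is not None and s.circ_id not in dec:
            continue
        if duplex_threshold is not None and s.duplex_score < duplex_threshold:
            continue
        by_pair.setdefault((s.circ_id, s.mirna_id), []).append(s)

    g = nx.Graph()
    for (circ, mir), ss in sorted(by_pair.items()):
        best = min(ss, key=lambda s: (SITE_CLASS_RANK[s.site_class], -s.duplex_score))
        g.add_node(f"circ:{circ}", kind="circRNA", label=circ)
        g.add_node(f"mir:{mir}", kind="miRNA", label=mir)
        g.add_edge(
            f"circ:{circ}", f"mir:{mir}",
            circ_id=circ, mirna_id=mir,
            best_site=best.site_class, site_count=len(ss),
            best_score=max(s.duplex_score for s in ss),
        )
    return CeRNANetwork(g)


def export_network(net: CeRNANetwork, path: str, fmt: str = "edge-list") -> None:
    """Write the network as edge-list TSV, SIF, or GraphML."""
    if fmt == "edge-list":
        with open(path, "w") as fh:
            fh.write("circ_id\tmirna_id\tsource_type\ttarget_type\tbest_site\tsite_count\tbest_score\n")
            for e in sorted(net.edges, key=lambda e: (e.circ_id, e.mirna_id)):
                fh.write(
                    f"{e.circ_id}\t{e.mirna_id}\tcircRNA\tmiRNA\t"
                    f"{e.best_site}\t{e.site_count}\t{e.best_score:g}\n"
                )
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in sorted(net.edges, key=lambda e: (e.circ_id, e.mirna_id)):
                fh.write(f"{e.circ_id}\tsponges\t{e.mirna_id}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown network format: {fmt}")


def import_edge_list(path: str) -> CeRNANetwork:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            circ, mir = vals["circ_id"], vals["mirna_id"]
            g.add_node(f"circ:{circ}", kind="circRNA", label=circ)
            g.add_node(f"mir:{mir}", kind="miRNA", label=mir)
            g.add_edge(
                f"circ:{circ}", f"mir:{mir}",
                circ_id=circ, mirna_id=mir,
                best_site=vals["best_site"],
                site_count=int(vals["site_count"]),
                best_score=float(vals["best_score"]),
            )
    return CeRNANetwork(g)
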