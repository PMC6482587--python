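"""Hypergeometric over-representation analysis of circRNA host genes.

Given a study set (host genes of differentially expressed circRNAs) and a
term-to-gene annotation map, each term's upper-tail hypergeometric P is

    P = sum_{k=x}^{min(n,K)} C(K,k) C(N-K,n-k) / C(N,n)

with x study genes in the term, n the study size, K the term size and N the
background universe size.  Exact rational combinatorics are used for
N <= 2000 and a log-space survival function beyond that; Benjamini-Hochberg
controls the FDR across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

EXACT_LIMIT = 2000


def hypergeom_upper_tail(x: int, K: int, n: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= x <= min(n, K) <= N and K <= N and n <= N and min(K, n) >= 0):
        raise ValueError(f"impossible margins: x={x} K={K} n={n} N={N}")
    if x == 0:
        return 1.0
    if N <= EXACT_LIMIT:
        total = Fraction(0)
        denom = comb(N, n)
        for k in range(x, min(n, K) + 1):
            total += Fraction(comb(K, k) * comb(N - K, n - k), denom)
        return float(total)
    return float(stats.hypergeom.sf(x - 1, N, K, n))


@dataclass
class AnnotationMap:
    """term -> gene-set map over a background universe."""

    term_genes: Dict[str, Set[str]]
    term_names: Dict[str, str] = field(default_factory=dict)
    term_namespaces: Dict[str, str] = field(default_factory=dict)
    universe: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.term_genes.values()) if self.term_genes else set()
        for t, genes in self.term_genes.items():
            if not genes:
                raise ValueError(f"term {t} has an empty gene set")
            stray = genes - self.universe
            if stray:
                raise ValueError(f"term {t} annotates genes outside the universe: {sorted(stray)[:3]}")

    @classmethod
    def from_tsv(
        cls,
        pairs_path: str,
        meta_path: Optional[str] = None,
        universe: Optional[Iterable[str]] = None,
    ) -> "AnnotationMap":
        """2-column TSV (term_id, gene_id); optional metadata TSV with columns
        term_id, name[, namespace]."""
        term_genes: Dict[str, Set[str]] = {}
        with open(pairs_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, gene = line.split("\t")[:2]
                term_genes.setdefault(term, set()).add(gene)
        names: Dict[str, str] = {}
        namespaces: Dict[str, str] = {}
        if meta_path:
            with open(meta_path) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) >= 2:
                        names[parts[0]] = parts[1]
                    if len(parts) >= 3:
                        namespaces[parts[0]] = parts[2]
        uni = set(universe) if universe is not None else set()
        if uni:
            term_genes = {
                t: gs & uni for t, gs in term_genes.items() if gs & uni
            }
        return cls(term_genes, names, namespaces, uni)

    @classmethod
    def from_gmt(cls, path: str, universe: Optional[Iterable[str]] = None) -> "AnnotationMap":
        term_genes: Dict[str, Set[str]] = {}
        names: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                term, name, genes = parts[0], parts[1], set(parts[2:])
                term_genes[term] = genes
                names[term] = name
        uni = set(universe) if universe is not None else set()
        if uni:
            term_genes = {t: gs & uni for t, gs in term_genes.items() if gs & uni}
        return cls(term_genes, names, universe=uni)


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    namespace: str
    x: int  # study genes in term
    n: int  # study size
    K: int  # term size in universe
    N: int  # universe size
    p_value: float
    q_value: float = float("nan")
    genes: Tuple[str, ...] = ()


def enrich(
    study_genes: Iterable[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Over-representation test of the study set against every term.

    Study genes outside the background universe are dropped with a warning.
    Terms with at least one study gene are tested, BH-corrected, and returned
    sorted by ascending P.
    """
    if not annotation.universe:
        raise ValueError("annotation has an empty background universe")
    study = set(study_genes)
    inside = study & annotation.universe
    if len(inside) < len(study):
        warnings.warn(
            f"{len(study) - len(inside)} study genes outside the universe were dropped",
            stacklevel=2,
        )
    n, N = len(inside), len(annotation.universe)
    results: List[EnrichmentResult] = []
    for term, genes in annotation.term_genes.items():
        hit = inside & genes
        if not hit:
            continue
        p = hypergeom_upper_tail(len(hit), len(genes), n, N)
        results.append(
            EnrichmentResult(
                term_id=term,
                name=annotation.term_names.get(term, term),
                namespace=annotation.term_namespaces.get(term, ""),
                x=len(hit), n=n, K=len(genes), N=N,
                p_value=p, genes=tuple(sorted(hit)),
            )
        )
    if results:
        qs = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def significant(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> List[EnrichmentResult]:
    return [r for r in results if r.q_value < alpha]


def summarize_pathways(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Pathway summary table: id, name, S (annotated study genes), TS (study
    size), P — ascending by P."""
    rows = [
        {
            "pathway_id": r.term_id,
            "pathway_name": r.name,
            "S": r.x,
            "TS": r.n,
            "p_value": r.p_value,
            "q_value": r.q_value,
        }
        for r in sorted(results, key=lambda r: (r.p_value, r.term_id))
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "S", "TS", "p_value", "q_value"])


def write_enrichment(results: Sequence[EnrichmentResult], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "term_id": r.term_id, "name": r.name, "namespace": r.namespace,
                "x": r.x, "n": r.n, "K": r.K, "N": r.N,
                "p_value": r.p_value, "q_value": r.q_value,
                "genes": ",".join(r.genes),
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
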