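"""Junction-read quantification: FPKM, expression-interval binning,
length and origin distributions.

FPKM here uses back-splice junction fragments as the numerator and the
circRNA spliced length as the effective length:

    FPKM = counts * 1e9 / (spliced_length * library_size)

with library_size the sample's total mapped fragments (linear + junction).
An FPKM of zero occurs exactly where the junction count is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import percent
from .junctions import CircRNARecord

DEFAULT_BOUNDARIES = (0.1, 0.3, 3.57, 15.0, 60.0)
DEFAULT_LABELS = ("0-0.1", "0.1-0.3", "0.3-3.57", "3.57-15", "15-60", ">60")
GROUPS = {
    "0-0.1": "low",
    "0.1-0.3": "low",
    "0.3-3.57": "medium",
    "3.57-15": "medium",
    "15-60": "high",
    ">60": "high",
}


def compute_fpkm(counts: float, spliced_length: int, library_size: int) -> float:
    """Fragments per kilobase of spliced sequence per million mapped fragments."""
    if spliced_length <= 0:
        raise ValueError("spliced_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return counts * 1e9 / (spliced_length * library_size)


@dataclass
class IntervalBinning:
    boundaries: Tuple[float, ...] = DEFAULT_BOUNDARIES
    labels: Tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need one more label than boundaries")

    def assign(self, fpkm: float) -> str:
        """Half-open intervals [lo, hi): a value on a boundary belongs to the
        interval above it."""
        for b, lab in zip(self.boundaries, self.labels):
            if fpkm < b:
                return lab
        return self.labels[-1]


@dataclass
class ExpressionTable:
    counts: pd.DataFrame  # circ_id x sample, int
    fpkm: pd.DataFrame  # circ_id x sample, float
    library_sizes: pd.Series  # per sample
    spliced_length: pd.Series  # per circ_id

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def write(self, counts_path: str, fpkm_path: str) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="circ_id")
        self.fpkm.to_csv(fpkm_path, sep="\t", index_label="circ_id")


def build_expression_table(
    records: Sequence[CircRNARecord],
    library_sizes: Mapping[str, int],
) -> ExpressionTable:
    """Assemble counts and FPKM matrices from called circRNAs; also fills the
    per-sample fpkm dict on each record."""
    samples = list(library_sizes)
    index = [r.circ_id for r in records]
    counts = pd.DataFrame(
        [[r.junction_reads.get(s, 0) for s in samples] for r in records],
        index=index, columns=samples, dtype=int,
    )
    lengths = pd.Series(
        {r.circ_id: int(r.spliced_length or r.span) for r in records}
    ).reindex(index)
    libs = pd.Series(library_sizes, dtype=float)
    fpkm = counts * 1e9
    fpkm = fpkm.div(lengths, axis=0).div(libs, axis=1)
    for r in records:
        r.fpkm = {s: float(fpkm.at[r.circ_id, s]) for s in samples}
    return ExpressionTable(counts, fpkm, pd.Series(library_sizes), lengths)


def bin_expression(
    table: ExpressionTable, binning: Optional[IntervalBinning] = None
) -> pd.DataFrame:
    """Per-sample counts and percentages of expressed circRNAs per FPKM
    interval.  Percentages are relative to that sample's expressed-circRNA
    count, rounded half-up to 2 decimals.
    """
    binning = binning or IntervalBinning()
    rows = []
    for lab in binning.labels:
        row: Dict[str, object] = {"interval": lab, "group": GROUPS.get(lab, "")}
        rows.append(row)
    out = pd.DataFrame(rows).set_index("interval")
    for s in table.samples:
        vals = table.fpkm[s][table.counts[s] > 0]
        n = len(vals)
        assigned = vals.map(binning.assign)
        cnt = assigned.value_counts()
        out[f"{s}_n"] = [int(cnt.get(lab, 0)) for lab in binning.labels]
        out[f"{s}_pct"] = [
            percent(int(cnt.get(lab, 0)), n) if n else 0.0 for lab in binning.labels
        ]
    return out


def length_distribution(
    records: Sequence[CircRNARecord],
    bins: Optional[Sequence[float]] = None,
    threshold: int = 1000,
) -> Tuple[pd.DataFrame, float]:
    """Histogram of spliced lengths plus the fraction above `threshold` nt."""
    lengths = np.array(
        [r.spliced_length if r.spliced_length is not None else r.span for r in records],
        dtype=float,
    )
    if lengths.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"]), 0.0
    if bins is None:
        upper = max(float(lengths.max()), float(threshold)) + 1
        bins = np.arange(0, upper + 200, 200)
    hist, edges = np.histogram(lengths, bins=bins)
    df = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
    )
    frac = float((lengths > threshold).mean())
    return df, frac


def origin_distribution(records: Sequence[CircRNARecord]) -> Dict[str, float]:
    """Fractions of origin classes; sums to 1 over non-empty input."""
    if not records:
        return {}
    n = len(records)
    out: Dict[str, float] = {}
    for r in records:
        key = r.origin or "unclassified"
        out[key] = out.get(key, 0.0) + 1.0
    return {k: v / n for k, v in sorted(out.items())}
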