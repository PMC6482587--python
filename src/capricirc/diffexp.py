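"""Differential expression of circRNAs between two conditions.

Group means are arithmetic means of per-sample FPKM.  Significance comes
from a two-sided Fisher's exact test on pooled junction counts against
pooled library sizes; Benjamini-Hochberg q-values are reported alongside.
Fold changes are oriented b-over-a (RE/PE in the reference design) and a
circRNA whose mean is exactly zero in one group is stage-specific: its
log2 fold change is +/-infinity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionTable

logger = logging.getLogger(__name__)


@dataclass
class GroupDesign:
    group_a: str = "PE"
    group_b: str = "RE"
    sample_groups: Dict[str, str] = field(
        default_factory=lambda: {"PE1": "PE", "PE2": "PE", "RE1": "RE", "RE2": "RE"}
    )
    alpha: float = 0.05
    q_threshold: float = 0.01
    use_q: bool = False  # stricter optional gate on BH q instead of raw P

    def samples_in(self, group: str) -> List[str]:
        return [s for s, g in self.sample_groups.items() if g == group]

    def validate(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples not mapped to a group: {missing}")
        for g in (self.group_a, self.group_b):
            if not self.samples_in(g):
                raise ValueError(f"group {g} has no samples")


def group_means(table: ExpressionTable, design: GroupDesign) -> pd.DataFrame:
    """Per-circRNA arithmetic mean FPKM in each group (columns mean_a, mean_b)."""
    design.validate(table.samples)
    a = table.fpkm[design.samples_in(design.group_a)].mean(axis=1)
    b = table.fpkm[design.samples_in(design.group_b)].mean(axis=1)
    return pd.DataFrame({"mean_a": a, "mean_b": b})


def fold_change(mean_a: float, mean_b: float) -> Tuple[float, float, str]:
    """(log2fc, linear fold, specificity) for one circRNA.

    log2fc = log2(mean_b / mean_a); the linear fold is reported in the
    larger-over-smaller orientation, as printed tables do.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if mean_a == 0 and mean_b == 0:
        raise ValueError("fold change undefined when both means are zero")
    if mean_a == 0:
        return math.inf, math.inf, "b_specific"
    if mean_b == 0:
        return -math.inf, math.inf, "a_specific"
    ratio = mean_b / mean_a
    return math.log2(ratio), max(ratio, 1.0 / ratio), "co_expressed"


def fisher_test(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Two-sided Fisher exact P on [[count_a, count_b], [lib_a-count_a,
    lib_b-count_b]].  Counts are pooled within group before testing."""
    if min(count_a, count_b) < 0:
        raise ValueError("negative counts")
    if count_a > lib_a or count_b > lib_b:
        raise ValueError("counts exceed library sizes")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    table = [[count_a, count_b], [lib_a - count_a, lib_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    table: ExpressionTable,
    design: Optional[GroupDesign] = None,
) -> pd.DataFrame:
    """Full per-circRNA differential table.

    Replicate junction counts are pooled within each group for the Fisher
    test; group means use per-sample FPKM.  circRNAs with zero mean in both
    groups are excluded (logged).  Columns mirror the reporting layout:
    per-sample FPKM, group means, log2fc, fold, p, q, regulation,
    specificity, significant.
    """
    design = design or GroupDesign()
    means = group_means(table, design)
    testable = means[(means.mean_a > 0) | (means.mean_b > 0)]
    dropped = len(means) - len(testable)
    if dropped:
        logger.info("excluded %d circRNAs with zero expression in both groups", dropped)

    samples_a = design.samples_in(design.group_a)
    samples_b = design.samples_in(design.group_b)
    lib_a = int(table.library_sizes[samples_a].sum())
    lib_b = int(table.library_sizes[samples_b].sum())

    rows = []
    for circ_id, m in testable.iterrows():
        log2fc, fold, spec = fold_change(m.mean_a, m.mean_b)
        ca = int(table.counts.loc[circ_id, samples_a].sum())
        cb = int(table.counts.loc[circ_id, samples_b].sum())
        p = fisher_test(ca, cb, lib_a, lib_b)
        if log2fc > 0:
            reg = "up"
        elif log2fc < 0:
            reg = "down"
        else:
            reg = "unchanged"
        row = {"circ_id": circ_id}
        for s in table.samples:
            row[f"fpkm_{s}"] = float(table.fpkm.at[circ_id, s])
        row.update(
            mean_a=float(m.mean_a), mean_b=float(m.mean_b),
            log2fc=log2fc, fold=fold, p_value=p,
            regulation=reg, specificity=spec,
            count_a=ca, count_b=cb,
        )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("circ_id")
    if df.empty:
        df["q_value"] = []
        df["significant"] = []
        return df
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    if design.use_q:
        df["significant"] = df["q_value"] < design.q_threshold
    else:
        df["significant"] = df["p_value"] < design.alpha
    return df


def classify_dec(df: pd.DataFrame, design: Optional[GroupDesign] = None) -> Dict[str, int]:
    """Summary partition of the differentially expressed circRNAs (DECs).

    Conservation identities hold by construction: up + down (+ unchanged)
    equals the DEC count, as does a_specific + b_specific + co_expressed.
    """
    dec = df[df["significant"]]
    return {
        "n_tested": int(len(df)),
        "n_dec": int(len(dec)),
        "n_up": int((dec["regulation"] == "up").sum()),
        "n_down": int((dec["regulation"] == "down").sum()),
        "n_unchanged": int((dec["regulation"] == "unchanged").sum()),
        "n_a_specific": int((dec["specificity"] == "a_specific").sum()),
        "n_b_specific": int((dec["specificity"] == "b_specific").sum()),
        "n_co_expressed": int((dec["specificity"] == "co_expressed").sum()),
    }


def format_dec_table(df: pd.DataFrame) -> pd.DataFrame:
    """Reporting precision: linear fold to 2 decimals, log2fc to 4."""
    out = df.copy()
    out["fold"] = out["fold"].map(
        lambda v: float("inf") if math.isinf(v) else round(v, 2)
    )
    out["log2fc"] = out["log2fc"].map(
        lambda v: v if math.isinf(v) else round(v, 4)
    )
    return out


def volcano_data(df: pd.DataFrame) -> pd.DataFrame:
    """log2fc vs -log10 P with the five-way class of the volcano plot:
    up / down / a_specific / b_specific / not significant."""
    def klass(row):
        if not row["significant"]:
            return "ns"
        if row["specificity"] == "a_specific":
            return "a_specific"
        if row["specificity"] == "b_specific":
            return "b_specific"
        return row["regulation"]

    out = pd.DataFrame(
        {
            "log2fc": df["log2fc"],
            "neg_log10_p": -np.log10(df["p_value"].clip(lower=1e-300)),
            "class": df.apply(klass, axis=1) if len(df) else [],
        }
    )
    return out
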