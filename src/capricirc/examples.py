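"""Worked-example inputs from the published goat endometrium circRNA study.

These are printed table values from the sequencing experiment the pipeline
models: per-sample read counts from the run overview, candidate back-splice
read counts, the expression-interval example, and the per-sample FPKM rows of
the top up-/down-regulated circRNAs.  They serve as inputs to the package's
calculators so the printed ratios, percentages and fold changes can be
recomputed and checked; nothing here is produced by this package.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from ._util import percent
from .diffexp import fold_change, group_means  # noqa: F401  (re-export for examples)

#: sample -> (raw reads, valid/clean reads)
SEQUENCING_OVERVIEW: Dict[str, Tuple[int, int]] = {
    "PE1": (120_000_000, 97_237_044),
    "PE2": (120_000_000, 90_947_840),
    "RE1": (120_000_000, 93_492_408),
    "RE2": (120_000_000, 94_273_656),
}

#: sample -> candidate back-spliced junction reads
CANDIDATE_BSJ_READS: Dict[str, int] = {
    "PE1": 924_831,
    "PE2": 911_567,
    "RE1": 1_490_765,
    "RE2": 1_895_346,
}

#: sample -> detected circRNA count
CIRC_COUNTS: Dict[str, int] = {"PE1": 7_968, "PE2": 12_114, "RE1": 6_980, "RE2": 9_188}

#: the lowest expression interval (FPKM 0-0.1) example: PE1 had 20 of 7,968
LOW_BIN_EXAMPLE = {"count": 20, "total": CIRC_COUNTS["PE1"]}


class DECExampleRow:
    """One published differential-expression row: per-sample FPKM plus the
    group means used for the printed fold change.

    For most rows the printed group means reconcile with the printed fold
    change; for circRNA9423 the printed PE mean (1.87) is itself rounded, so
    the PE mean is recomputed from the per-sample values (0, 3.75)."""

    def __init__(
        self,
        circ_id: str,
        per_sample: Dict[str, float],
        mean_pe: Optional[float],
        mean_re: Optional[float],
    ) -> None:
        self.circ_id = circ_id
        self.per_sample = per_sample
        self.mean_pe = (
            mean_pe
            if mean_pe is not None
            else (per_sample["PE1"] + per_sample["PE2"]) / 2.0
        )
        self.mean_re = (
            mean_re
            if mean_re is not None
            else (per_sample["RE1"] + per_sample["RE2"]) / 2.0
        )

    def fold(self) -> Tuple[float, float, str]:
        """(log2fc, linear fold, specificity), RE over PE orientation."""
        return fold_change(self.mean_pe, self.mean_re)


DEC_EXAMPLES: List[DECExampleRow] = [
    DECExampleRow("circRNA5540", {"PE1": 129, "PE2": 148, "RE1": 18, "RE2": 0}, 138.64, 9.02),
    DECExampleRow("circRNA3165", {"PE1": 36, "PE2": 39.31, "RE1": 12, "RE2": 18}, 37.64, 15.28),
    DECExampleRow("circRNA3895", {"PE1": 56, "PE2": 68.9, "RE1": 14, "RE2": 0}, 62.32, 6.88),
    DECExampleRow("circRNA9423", {"PE1": 0, "PE2": 3.75, "RE1": 23, "RE2": 27}, None, 24.73),
    DECExampleRow("circRNA5990", {"PE1": 6.7, "PE2": 2.88, "RE1": 21, "RE2": 26}, 4.78, 23.56),
]


def valid_ratio_pct(sample: str) -> float:
    raw, valid = SEQUENCING_OVERVIEW[sample]
    return percent(valid, raw)


def candidate_fraction_pct(sample: str) -> float:
    raw, valid = SEQUENCING_OVERVIEW[sample]
    return percent(CANDIDATE_BSJ_READS[sample], valid)


def low_bin_pct() -> float:
    return percent(LOW_BIN_EXAMPLE["count"], LOW_BIN_EXAMPLE["total"])
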