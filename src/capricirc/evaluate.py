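"""Truth-set evaluation of caller and differential-expression output."""

from __future__ import annotations

from typing import Dict, Iterable, Sequence, Set, Tuple

import pandas as pd

from .junctions import CircRNARecord
from .synthetic import TruthCircRNA


def _truth_keys(truth: Sequence[TruthCircRNA]) -> Set[Tuple[str, int, int, str]]:
    return {t.key for t in truth}


def evaluate_calls(
    records: Sequence[CircRNARecord],
    truth: Sequence[TruthCircRNA],
) -> Dict[str, float]:
    """Precision and recall of called junctions against the planted truth.

    A call matches a truth entry iff chromosome, junction span and strand are
    identical (exact-coordinate matching; the caller is expected to be
    base-precise on these genomes).
    """
    truth_keys = _truth_keys(truth)
    call_keys = {r.key for r in records}
    tp = len(call_keys & truth_keys)
    precision = tp / len(call_keys) if call_keys else 0.0
    recall = tp / len(truth_keys) if truth_keys else 0.0
    return {
        "n_called": float(len(call_keys)),
        "n_truth": float(len(truth_keys)),
        "true_positives": float(tp),
        "precision": precision,
        "recall": recall,
    }


def differential_sensitivity(
    dec_table: pd.DataFrame,
    records: Sequence[CircRNARecord],
    truth: Sequence[TruthCircRNA],
) -> Dict[str, float]:
    """Fraction of planted differential circRNAs that are both called and
    flagged significant."""
    key_to_circ = {r.key: r.circ_id for r in records}
    diff_truth = [t for t in truth if t.is_differential]
    if not diff_truth:
        return {"n_true_differential": 0.0, "sensitivity": 0.0}
    sig = set(dec_table.index[dec_table["significant"]]) if len(dec_table) else set()
    hit = sum(
        1 for t in diff_truth if key_to_circ.get(t.key) in sig
    )
    return {
        "n_true_differential": float(len(diff_truth)),
        "n_recovered": float(hit),
        "sensitivity": hit / len(diff_truth),
    }
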