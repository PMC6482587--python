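"""Small shared helpers: strand arithmetic and table-style rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as printed tables conventionally do.

    Python's built-in round() is banker's rounding, which disagrees with
    table formatting on exact .5 ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to `ndigits` decimals."""
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
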