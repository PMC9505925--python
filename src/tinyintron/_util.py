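"""Shared helpers: half-up percentage rounding and RNA/DNA alphabet maps."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

RNA_BASES = ("A", "C", "G", "U")
DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed percentages).

    Python's built-in round() is banker's rounding, which would turn
    e.g. 18.135 into 18.13; reported shares use half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded; exact for integer inputs."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    val = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")
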