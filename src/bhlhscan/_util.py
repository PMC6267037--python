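"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention used for all printed
    percentages), avoiding banker's rounding surprises on two-decimal output."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    if total == 0:
        raise ValueError("percentage undefined for total=0")
    return round_half_up(100.0 * count / total, ndigits)
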