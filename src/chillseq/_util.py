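"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

VALID_DNA = frozenset("ACGTN")
VALID_BASES = frozenset("ACGTU")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention used for all
    printed percentages), avoiding banker's rounding surprises."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """numerator/denominator as a percentage, round-half-up; 0.0 when the
    denominator is zero."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result uses DNA letters)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def normalize_rna(seq: str) -> str:
    """Uppercase and rewrite U as T for internal comparisons."""
    return seq.upper().replace("U", "T")
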