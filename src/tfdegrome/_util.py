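"""Small shared helpers: symbol canonicalization and percentage rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal


def canon(symbol: str) -> str:
    """Canonicalize a gene symbol: strip surrounding whitespace, uppercase.

    No alias resolution is attempted; sources are matched on plain symbols.
    """
    return symbol.strip().upper()


def pct_one_decimal(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator rounded half-even to one decimal.

    Raw fractions are kept alongside wherever this is reported; the rounded
    figure exists only for human-readable tables.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))
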