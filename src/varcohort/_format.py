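"""Percentage arithmetic with the half-up rounding used in the report tables."""

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(value: float | Fraction, ndigits: int = 2) -> float:
    """Round half away from zero (12.345 -> 12.35 at 2 digits), unlike banker's rounding."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(str(value))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """100*count/total rounded half-up; exact rational division before rounding."""
    if total <= 0:
        raise ZeroDivisionError("percentage undefined for non-positive total")
    return round_half_up(Fraction(100 * count, total), ndigits)


def fmt_percent(count: int, total: int, ndigits: int = 2) -> str:
    """Render ``percent`` with a fixed number of decimals, e.g. '52.78'."""
    return f"{percent(count, total, ndigits):.{ndigits}f}"
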