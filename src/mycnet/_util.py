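"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Python's builtin ``round`` is banker's rounding; report tables here follow
    the half-up convention (62.5 -> 63 at integer precision).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct_half_up(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Percentage 100*numerator/denominator rounded half-up to ndigits."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)
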