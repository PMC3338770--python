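"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed tables do.

    Python's built-in ``round`` is banker's rounding; published tables in
    this field round 0.25 -> 0.3, so percent columns use this instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float) -> float:
    """Percent formatting convention: 1 decimal place, 2 below 1%."""
    return round_half_up(x, 2 if x < 1.0 else 1)
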