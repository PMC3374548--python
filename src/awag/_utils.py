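"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as the reference tables render.

    Python's built-in ``round`` is banker's rounding; survey tables
    conventionally print 44.35 as 44.4, not 44.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(rate: float, ndigits: int = 1) -> float:
    """Render a proportion in [0, 1] as a percentage, half-up rounded."""
    return round_half_up(rate * 100.0, ndigits)
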