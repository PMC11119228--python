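"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (printed-table style).

    Python's builtin ``round`` is banker's rounding; clinical tables round 0.05
    up, so 82.45 -> 82.5 at one decimal.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def nearest_int(x: float) -> int:
    """Nearest integer with .5 rounded up (count reconstruction from rates)."""
    import math

    return int(math.floor(x + 0.5))
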