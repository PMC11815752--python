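"""Half-up decimal rounding used for all displayed quantities.

Python's built-in ``round`` is banker's (half-to-even) rounding; regulatory
tables round half away from zero (50.6/60 = 0.8433 -> 0.84, 5/7*100 = 71.43
-> 71.4, 0.845 -> 0.85).  All internal arithmetic stays unrounded; these
helpers are applied only when a value is reported.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Uses the shortest-repr decimalisation of the float so that values such
    as 0.845 behave as printed rather than as their binary approximation.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
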