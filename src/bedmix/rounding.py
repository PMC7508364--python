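"""Display rounding.

Published bed-management tables round half away from zero (commercial
rounding), not banker's style: occupancy rates are printed as integer
percentages and every other indicator or index to two decimals.  All
composition inside the package uses unrounded values; these helpers exist
only for display and for threshold classification, which is defined on the
printed precision.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    ``repr(float(x))`` is used as the decimal source so that binary floats
    round on their shortest decimal representation (36.375 -> 36.38, not
    whatever the nearest binary double happens to be).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
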