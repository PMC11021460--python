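"""Small shared helpers."""

from __future__ import annotations

import decimal
from fractions import Fraction

__all__ = ["round_half_up"]


def round_half_up(x, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention).

    Python's built-in ``round`` is banker's rounding; concentrations,
    yields and rates are reported with conventional half-up rounding
    (125.45 -> 125.5).  Exact ``Fraction`` inputs are rounded exactly.
    """
    if isinstance(x, Fraction):
        d = decimal.Decimal(x.numerator) / decimal.Decimal(x.denominator)
    else:
        d = decimal.Decimal(repr(float(x)))
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))
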