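"""Reporting-layer rounding.

Point estimates are carried at full precision everywhere; rounding
happens only when values are printed or when a summary is explicitly
defined over rounded values.  Rounding is half-away-from-zero (so 87.5%
reports as 88, 0.7255 as 0.726), which is what the study tables use —
Python's built-in ``round`` is banker's rounding and differs on ties.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
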