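"""Half-up decimal rounding for report tables.

Python's built-in ``round`` is banker's rounding; report tables in this
package round halves away from zero (0.7315 -> 0.732), the convention of
the spreadsheet/statistics software era the emulated study used. Floats
are first quantized a few guard digits below the target precision so
that binary representation error (e.g. ``87.05`` stored as
``87.04999...``) does not flip the half-way direction.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]

_GUARD_DIGITS = 6


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round ``value`` to ``ndigits`` decimals, halves away from zero."""
    d = Decimal(repr(float(value)))
    d = d.quantize(
        Decimal(1).scaleb(-(ndigits + _GUARD_DIGITS)), rounding=ROUND_HALF_UP
    )
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
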