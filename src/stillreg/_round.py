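"""Half-up decimal rounding for report tables."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention).

    Python's builtin ``round`` is banker's rounding; report tables round
    halves up, so 34.95 -> 35.0 rather than 34.9.
    """
    if x is None:
        return float("nan")
    x = float(x)
    if not math.isfinite(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))
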