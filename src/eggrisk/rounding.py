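"""Display rounding to significant figures.

Two conventions are needed to reproduce published tables: conventional
half-away-from-zero rounding (risk values such as THQ 0.000649 -> 0.0006)
and truncation toward zero (exposure tables where EDI 0.0025973 is shown
as 0.002 and the displayed weekly/monthly intakes are formed from the
truncated value).
"""

from __future__ import annotations

import math
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round_display", "truncate_display"]


def _to_sigfigs(x: float, sig: int, mode: str) -> float:
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(abs(x)))
    exp = d.adjusted()  # floor(log10(|x|))
    scaled = d.scaleb(-(exp - sig + 1))
    q = scaled.quantize(Decimal(1), rounding=mode).scaleb(exp - sig + 1)
    return math.copysign(float(q), x)


def round_display(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures, halves away from zero."""
    return _to_sigfigs(x, sig, ROUND_HALF_UP)


def truncate_display(x: float, sig: int = 1) -> float:
    """Truncate toward zero to ``sig`` significant figures."""
    return _to_sigfigs(x, sig, ROUND_DOWN)
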