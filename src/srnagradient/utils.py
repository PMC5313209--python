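"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def pct_half_up(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage rounded half-up to `ndigits` (3.125% -> 3.13, not 3.12).

    Report tables round this way so that shares such as 3/96 print as the
    conventional 3.13 rather than banker's-rounded 3.12.
    """
    if denominator == 0:
        return 0.0
    q = Decimal(str(numerator)) / Decimal(str(denominator)) * 100
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))
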