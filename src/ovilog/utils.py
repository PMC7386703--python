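"""Small shared numeric helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables),
    unlike banker's rounding of the builtin."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
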