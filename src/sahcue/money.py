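"""Small money helpers shared across modules.

Drug costing works in exact ``Decimal`` cents so printed drug tables are
reproduced bit-exactly at two decimals; cohort economics work in floats
(calibrated per-patient anchors are non-terminating decimals) and use
:func:`round_half_up` only at display time.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

CENT = Decimal("0.01")


def cents(amount: float | str | Decimal) -> Decimal:
    """Quantize ``amount`` to exact cents, rounding half-up."""
    return Decimal(str(amount)).quantize(CENT, rounding=ROUND_HALF_UP)


def round_half_up(amount: float, decimals: int = 0) -> float:
    """Half-up rounding (1.5 -> 2, 2.5 -> 3), unlike banker's ``round``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(amount)).quantize(q, rounding=ROUND_HALF_UP))
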