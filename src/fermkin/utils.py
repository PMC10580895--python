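"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, matching how printed tables round.

    Python's built-in ``round`` uses banker's rounding (3.125 -> 3.12);
    published tables almost always use half-up (3.125 -> 3.13).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(value: float, sig: int) -> float:
    """Round to ``sig`` significant figures, half-up."""
    value = float(value)
    if value == 0:
        return 0.0
    d = Decimal(repr(value))
    shift = sig - d.adjusted() - 1
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))
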