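"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_half_up_pct"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals (the
    convention used for the reported percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_pct(part: float, total: float, decimals: int = 1) -> float:
    """100 * part / total, rounded half-up to ``decimals`` places."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * part / total, decimals)
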