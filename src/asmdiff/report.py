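"""Ratio reporting helpers.

Reported percentages use half-up decimal rounding (the convention of
printed one-decimal figures such as 72.8%), and report lines always
carry the raw counts beside the ratio.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["percentage", "ratio_line"]


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


def ratio_line(label: str, numerator: int, denominator: int, decimals: int = 1) -> str:
    """Human-readable ratio statement with its raw counts."""
    pct = percentage(numerator, denominator, decimals)
    return f"{label}: {numerator:,} / {denominator:,} ({pct}%)"
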