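"""Small reporting helpers: the count-ratio percentages quoted in results
tables are always 100 * ratio rounded half-up to a fixed number of decimals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator/denominator, rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def per_day_rate(abs_change_pct: float, days: float, decimals: int = 2) -> float:
    """Absolute percent-methylation change normalized per day elapsed."""
    if days <= 0:
        raise ValueError("days elapsed must be positive")
    value = Decimal(str(abs_change_pct)) / Decimal(str(days))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
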