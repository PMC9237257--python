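"""Percentage formatting used across report tables.

All printed percentages in the report set use round-half-up at two decimals
(``258/19719 -> "1.31%"``), computed in decimal arithmetic so that binary
float representation never flips a half-way case.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, getcontext

getcontext().prec = 40


def pct_round_half_up(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up.

    Raises ``ValueError`` on a zero denominator.
    """
    if denominator == 0:
        raise ValueError("percentage denominator is zero")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(str(numerator)) * 100 / Decimal(str(denominator))).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def format_pct(numerator: float, denominator: float, decimals: int = 2) -> str:
    """Format as the reports print it, e.g. ``"1.31%"``."""
    return f"{pct_round_half_up(numerator, denominator, decimals):.{decimals}f}%"


def format_count_pct(count: int, denominator: float, decimals: int = 2) -> str:
    """``"30 (33.33%)"`` style cell used in the cis-element summary table."""
    return f"{count} ({format_pct(count, denominator, decimals)})"
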