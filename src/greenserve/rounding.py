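"""Reporting-layer rounding.

All percentages in emitted tables use round-half-up at 2 decimals; internal
computation stays at full float precision and rounding happens only when a
number is written into a report.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimals.

    Python's built-in ``round`` is banker's rounding; report tables follow
    the half-up convention instead (2.345 -> 2.35 at 2 decimals).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def ratio_percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up.

    Returns 0.0 for a zero denominator so empty zones report 0.00% rather
    than raising in the middle of a table build.
    """
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)
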