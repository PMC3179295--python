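"""Small shared helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (half-up), as printed reports expect.

    Python's built-in round is banker's rounding; report arithmetic
    (percentages, ratios, mm pitches) uses conventional half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
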