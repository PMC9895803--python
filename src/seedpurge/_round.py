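"""Half-up decimal rounding, the display convention used throughout.

Python's built-in ``round`` is banker's rounding; printed tables in the
field round half away from zero, so 46.985 must display as 46.99.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
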