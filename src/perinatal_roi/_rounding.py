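"""Rounding conventions shared across the model.

Reported counts and monetary amounts round half away from zero;
intermediate products keep full floating-point precision.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
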