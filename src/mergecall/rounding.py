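"""Half-away-from-zero decimal rounding for printed percentages/statistics."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_away"]


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (unlike banker's ``round``)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
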