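"""Half-up rounding for displayed percentages and similarities."""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (0.5 -> 1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    out = float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
    return out if ndigits > 0 else float(int(out))
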