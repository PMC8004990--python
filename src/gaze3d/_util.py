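"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (report-table convention).

    Python's builtin ``round`` is banker's rounding; report tables use
    half-up, so 0.825 -> 0.83.  Goes through the shortest decimal repr of
    the float to avoid spurious binary tie-breaking.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
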