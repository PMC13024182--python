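"""Shared numeric and sequence helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(value, digits: int = 2) -> float:
    """Round half away from zero (the convention used in printed tables).

    Accepts a float or an exact (numerator, denominator) pair; the pair form
    avoids binary-float ties like 0.125 rounding the wrong way.
    """
    if isinstance(value, tuple):
        num, den = value
        d = Decimal(num) / Decimal(den)
    else:
        d = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-digits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator, denominator, digits: int = 2) -> float:
    """Exact percentage of two integers, rounded half-up."""
    return round_half_up((100 * numerator, denominator), digits)
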