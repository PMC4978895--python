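"""Half-to-even display rounding shared by the table-facing modules.

Display values mirror the conventions of the published screen tables:
allele frequencies in 1e-5-per-haploid-genome units at one decimal,
spectrum percentages at one decimal.  Exact rational quantities are rounded
through ``decimal`` so that true ties (e.g. 93.75) resolve half-to-even
instead of through binary floating point.
"""
from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction


def half_even(x: float, ndigits: int) -> float:
    """Round a float half-to-even at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(x).quantize(q, rounding=ROUND_HALF_EVEN))


def ratio_display(numerator: int, denominator: int, scale: int, ndigits: int) -> float:
    """Round the exact rational ``scale * numerator / denominator`` half-to-even.

    Used for frequency displays (scale 100000, one decimal) and percentage
    displays (scale 100, one decimal), where the operands are exact integers
    and ties must not be perturbed by binary floating point.
    """
    frac = Fraction(numerator * scale, denominator)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))
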