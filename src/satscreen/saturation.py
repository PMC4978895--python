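"""Poisson zero-class estimation of unidentified genes (screen saturation).

If the number of alleles recovered per mutable gene is Poisson with mean
``lambda``, the probability that a gene yielded no allele — and therefore
went unidentified — is the zero class ``P(0) = exp(-lambda)``.  With ``N``
identified genes the expected number of unidentified genes is::

    N(0) = N * exp(-lambda) / (1 - exp(-lambda))

``lambda`` is estimated as total alleles divided by the number of identified
genes, i.e. the observed (zero-truncated) mean.  This estimator slightly
overstates the true Poisson mean because genes with zero alleles cannot
enter the average; the bias is deliberate fidelity to the screen-genetics
convention and is quantified (not corrected) in the test suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._display import half_even
from .tables import AlleleTable, ScreenDesign, ScreenTableError

__all__ = ["SaturationResult", "saturation_estimate", "saturation_by_series"]


@dataclass(frozen=True)
class SaturationResult:
    """Zero-class saturation estimate for one selection of screen series.

    Attributes hold unrounded values; ``*_display`` properties round the way
    screen tables are printed (lambda to one decimal, P0 to four, N0 to
    three).  ``summary()`` renders a small report table.
    """

    allele_counts: tuple[int, ...]
    selection: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.allele_counts:
            raise ScreenTableError("saturation estimate needs at least one identified gene")
        if any(c < 1 for c in self.allele_counts):
            raise ScreenTableError(
                "allele counts must all be >= 1 (zero-allele genes are by "
                "definition unidentified and must be excluded)"
            )

    # -- estimates -------------------------------------------------------
    @property
    def N(self) -> int:
        """Number of identified genes."""
        return len(self.allele_counts)

    @property
    def total_alleles(self) -> int:
        return sum(self.allele_counts)

    @property
    def lambda_(self) -> float:
        """Mean allele number per identified gene (zero-truncated mean)."""
        return self.total_alleles / self.N

    @property
    def P0(self) -> float:
        """Poisson zero-class probability exp(-lambda)."""
        return math.exp(-self.lambda_)

    @property
    def N0(self) -> float:
        """Expected number of unidentified genes N * P0 / (1 - P0)."""
        p0 = self.P0
        return self.N * p0 / (1.0 - p0)

    # -- display ---------------------------------------------------------
    @property
    def lambda_display(self) -> float:
        return half_even(self.lambda_, 1)

    @property
    def P0_display(self) -> float:
        return half_even(self.P0, 4)

    @property
    def N0_display(self) -> float:
        return half_even(self.N0, 3)

    def summary(self) -> str:
        sel = ",".join(self.selection) if self.selection else "(direct counts)"
        lines = [
            "Poisson zero-class saturation estimate",
            "=" * 46,
            f"{'series selection':<28}{sel}",
            f"{'identified genes N':<28}{self.N}",
            f"{'total alleles':<28}{self.total_alleles}",
            f"{'lambda (alleles/gene)':<28}{self.lambda_:.4f}  [{self.lambda_display:.1f}]",
            f"{'P(0) = exp(-lambda)':<28}{self.P0:.6f}  [{self.P0_display:.4f}]",
            f"{'N(0) unidentified genes':<28}{self.N0:.6f}  [{self.N0_display:.3f}]",
            "=" * 46,
        ]
        return "\n".join(lines)


def saturation_estimate(
    allele_counts: Sequence[int], selection: Iterable[str] | None = None
) -> SaturationResult:
    """Estimate screen saturation from per-gene allele counts (each >= 1)."""
    counts = tuple(int(c) for c in allele_counts)
    return SaturationResult(
        allele_counts=counts,
        selection=tuple(selection) if selection is not None else None,
    )


def saturation_by_series(
    table: AlleleTable, design: ScreenDesign, selection: Iterable[str]
) -> SaturationResult:
    """Saturation estimate for a selection of screen series.

    Per-gene counts are summed over the selected series; genes with zero
    total are excluded (they are the unidentified class being estimated).
    """
    sel = list(selection)
    if not sel:
        raise ScreenTableError("empty series selection")
    for sid in sel:
        design.get_series(sid)  # raises on unknown id
    per_gene = table.per_gene_counts(design.gene_ids, sel)
    counts = [c for c in per_gene.values() if c > 0]
    if not counts:
        raise ScreenTableError(
            f"no alleles isolated in series selection {sel!r}; saturation undefined"
        )
    return saturation_estimate(counts, selection=sel)
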