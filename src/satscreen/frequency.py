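"""Per-gene allele frequencies with eligibility-dependent denominators.

A gene's allele frequency along an axis (per mutagen or per background) is
its summed allele count over the contributing series divided by the summed
haploid genomes of those series — but only series whose background permits
isolation of the gene contribute to either sum.  A gene bypassed by the
rescue transgene excludes the transgene-rescue series from its denominator;
a gene suppressed in the acs-22 null background excludes those series.

Cells fall into three distinct states that round-trip through TSV output:

* defined with alleles (positive frequency),
* defined without alleles (eligible but empty; frequency 0.0),
* undefined (the gene is ineligible in every series of the axis key; "NA").

Display values are in 1e-5-per-haploid-genome units rounded half-to-even at
one decimal.  Column totals are sums of the *rounded* per-gene display
values: this summand convention is the only one under which the published
totals reproduce exactly, and it is therefore the package's convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._display import ratio_display
from .tables import AlleleTable, Background, Mutagen, ScreenDesign, ScreenTableError

__all__ = [
    "UndefinedCellError",
    "FrequencyCell",
    "FrequencyTable",
    "eligible_denominator",
    "frequency_table",
    "enrichment_ratio",
]

DISPLAY_SCALE = 100_000  # display unit: 1e-5 per haploid genome


class UndefinedCellError(ScreenTableError):
    """The gene is ineligible in every series contributing to the axis key."""


@dataclass(frozen=True)
class FrequencyCell:
    gene_id: str
    axis: str  # "mutagen" | "background"
    key: str
    count: int
    denominator: int
    freq_per_genome: float
    display_1e5: float  # rounded half-to-even, one decimal, 1e-5 units


def _axis_key(axis: str, key) -> tuple[str, object]:
    if axis == "mutagen":
        return axis, Mutagen(key)
    if axis == "background":
        return axis, Background(key)
    raise ScreenTableError(f"unknown axis {axis!r} (expected 'mutagen' or 'background')")


def eligible_denominator(
    gene_id: str, axis: str, key, design: ScreenDesign
) -> int:
    """Summed haploid genomes of the series contributing to a frequency cell.

    Mutagen axis: all series of that mutagen whose background permits the
    gene.  Background axis: all series (both mutagens) of that background,
    defined only if the background permits the gene.

    Raises :class:`UndefinedCellError` when no series contributes.
    """
    axis, key = _axis_key(axis, key)
    if axis == "mutagen":
        series = design.eligible_series(gene_id, mutagen=key)
    else:
        series = design.eligible_series(gene_id, background=key)
    if not series:
        raise UndefinedCellError(
            f"gene {gene_id!r} is ineligible in every series of {axis} {key.value!r}"
        )
    return sum(s.haploid_genomes for s in series)


def _cell(
    table: AlleleTable, design: ScreenDesign, gene_id: str, axis: str, key
) -> FrequencyCell:
    axis, key = _axis_key(axis, key)
    denom = eligible_denominator(gene_id, axis, key.value, design)
    if axis == "mutagen":
        series = design.eligible_series(gene_id, mutagen=key)
    else:
        series = design.eligible_series(gene_id, background=key)
    count = table.gene_total(gene_id, [s.series_id for s in series])
    return FrequencyCell(
        gene_id=gene_id,
        axis=axis,
        key=key.value,
        count=count,
        denominator=denom,
        freq_per_genome=count / denom,
        display_1e5=ratio_display(count, denom, DISPLAY_SCALE, 1),
    )


class FrequencyTable:
    """Frequency cells for every gene x axis key, plus column totals.

    Totals are per-(axis, key) sums of the rounded per-gene display values.
    """

    def __init__(self, cells: list[FrequencyCell]):
        self._cells = {(c.gene_id, c.axis, c.key): c for c in cells}

    def cell(self, gene_id: str, axis: str, key) -> FrequencyCell:
        axis, key = _axis_key(axis, key)
        try:
            return self._cells[(gene_id, axis, key.value)]
        except KeyError:
            raise UndefinedCellError(
                f"no defined {axis} cell {key.value!r} for gene {gene_id!r}"
            ) from None

    def display(self, gene_id: str, axis: str, key) -> float:
        return self.cell(gene_id, axis, key).display_1e5

    def has_cell(self, gene_id: str, axis: str, key) -> bool:
        axis, key = _axis_key(axis, key)
        return (gene_id, axis, key.value) in self._cells

    def total(self, axis: str, key) -> float:
        """Column total: sum of rounded per-gene display values (1e-5 units)."""
        axis, key = _axis_key(axis, key)
        vals = [
            c.display_1e5
            for c in self._cells.values()
            if c.axis == axis and c.key == key.value
        ]
        # each summand carries one decimal; re-round to kill float drift
        return round(sum(vals), 1)

    def totals(self) -> dict[tuple[str, str], float]:
        keys = {(c.axis, c.key) for c in self._cells.values()}
        return {(a, k): self.total(a, k) for a, k in sorted(keys)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": c.gene_id,
                "axis": c.axis,
                "key": c.key,
                "count": c.count,
                "denominator": c.denominator,
                "freq_per_genome": c.freq_per_genome,
                "freq_display_1e5": c.display_1e5,
            }
            for c in sorted(self._cells.values(), key=lambda c: (c.axis, c.key, c.gene_id))
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "axis", "key", "count", "denominator",
                "freq_per_genome", "freq_display_1e5",
            ],
        )

    def write_tsv(self, path: str | Path, design: ScreenDesign) -> None:
        """Write all gene x axis-key cells; undefined cells appear as NA."""
        rows = []
        for gene_id in design.gene_ids:
            for axis, keys in (("mutagen", Mutagen), ("background", Background)):
                for key in keys:
                    if self.has_cell(gene_id, axis, key.value):
                        c = self.cell(gene_id, axis, key.value)
                        rows.append(
                            {
                                "gene_id": gene_id, "axis": axis, "key": key.value,
                                "count": c.count, "denominator": c.denominator,
                                "freq_per_genome": f"{c.freq_per_genome:.10g}",
                                "freq_display_1e5": f"{c.display_1e5:.1f}",
                            }
                        )
                    else:
                        rows.append(
                            {
                                "gene_id": gene_id, "axis": axis, "key": key.value,
                                "count": "NA", "denominator": "NA",
                                "freq_per_genome": "NA", "freq_display_1e5": "NA",
                            }
                        )
        for (axis, key), tot in self.totals().items():
            rows.append(
                {
                    "gene_id": "TOTAL", "axis": axis, "key": key,
                    "count": "", "denominator": "",
                    "freq_per_genome": "", "freq_display_1e5": f"{tot:.1f}",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def frequency_table(table: AlleleTable, design: ScreenDesign) -> FrequencyTable:
    """Compute the full per-gene frequency table along both axes."""
    cells = []
    for gene_id in design.gene_ids:
        for axis, keys in (("mutagen", Mutagen), ("background", Background)):
            for key in keys:
                try:
                    cells.append(_cell(table, design, gene_id, axis, key.value))
                except UndefinedCellError:
                    continue
    return FrequencyTable(cells)


def enrichment_ratio(
    ftable: FrequencyTable, gene_id: str, numerator: str, denominator: str
) -> float:
    """Ratio of two background display frequencies for one gene.

    Quantifies background-specific enrichment (e.g. a class III gene isolated
    2.27-fold more frequently in the suppressor-null than the WT series).
    Computed on the rounded display values, matching the published arithmetic.
    """
    num = ftable.display(gene_id, "background", numerator)
    den = ftable.display(gene_id, "background", denominator)
    if den == 0:
        raise ScreenTableError(
            f"gene {gene_id!r}: zero denominator frequency in background {denominator!r}"
        )
    return num / den
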