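"""Typed containers and tab-separated I/O for forward-genetic screen bookkeeping.

A screen *design* couples the set of mutagenesis series (mutagen x genetic
background, each with a known number of screened haploid genomes) with the
per-gene attributes that decide in which backgrounds a gene's mutants can be
isolated at all: a multicopy rescue transgene bypasses re-isolation of the
genes it carries, and screening in a suppressor-null background prevents
isolation of genes whose mutant phenotype requires the suppressed pathway.
The *allele table* records how many independent mutant alleles of each
complementation group were isolated in each series.

All files are UTF-8 TSV with a header row; lines starting with ``#`` are
ignored.  Haploid genome counts are absolute integers; scientific notation
such as ``1.18e5`` is accepted on input.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Mutagen",
    "Background",
    "ScreenSeries",
    "GeneSpec",
    "ScreenDesign",
    "AlleleTable",
    "ValidationReport",
    "ScreenTableError",
    "ParseError",
    "read_design",
    "read_allele_table",
    "write_design",
    "write_allele_table",
    "validate",
    "load_reference_design",
    "load_reference_allele_table",
]


class ScreenTableError(ValueError):
    """Inconsistent or malformed screen table input."""


class ParseError(ScreenTableError):
    """A TSV file could not be parsed into the typed containers."""


class Mutagen(str, enum.Enum):
    EMS = "EMS"
    ENU = "ENU"


class Background(str, enum.Enum):
    """Mutagenesis background.

    ``TRANSGENE_RESCUE`` is a multicopy wild-type rescue transgene background
    (prevents re-isolation of the rescued genes); ``ACS22_NULL`` is a
    suppressor-null background (prevents isolation of genes whose supersized
    lipid-droplet phenotype depends on the ACS-22/DGAT-2 pathway).
    """

    WT = "WT"
    TRANSGENE_RESCUE = "TRANSGENE_RESCUE"
    ACS22_NULL = "ACS22_NULL"


@dataclass(frozen=True)
class ScreenSeries:
    """One mutagenesis series: a mutagen applied in one genetic background."""

    series_id: str
    mutagen: Mutagen
    background: Background
    haploid_genomes: int

    def __post_init__(self) -> None:
        if self.haploid_genomes <= 0:
            raise ScreenTableError(
                f"series {self.series_id!r}: haploid_genomes must be positive, "
                f"got {self.haploid_genomes}"
            )


@dataclass(frozen=True)
class GeneSpec:
    """A complementation group and its background-eligibility attributes.

    ``n_loci`` is 1 except for groups whose single isolate carries mutations
    in two unlinked loci (counted as one complementation group throughout).
    """

    gene_id: str
    linkage: str = "unknown"
    bypassed_by_transgene: bool = False
    suppressed_by_acs22: bool = False
    temperature_sensitive: bool = False
    n_loci: int = 1

    def __post_init__(self) -> None:
        if self.n_loci not in (1, 2):
            raise ScreenTableError(
                f"gene {self.gene_id!r}: n_loci must be 1 or 2, got {self.n_loci}"
            )

    def eligible_in(self, background: Background) -> bool:
        """Can an allele of this gene be isolated in the given background?"""
        if self.bypassed_by_transgene and background is Background.TRANSGENE_RESCUE:
            return False
        if self.suppressed_by_acs22 and background is Background.ACS22_NULL:
            return False
        return True


@dataclass
class ScreenDesign:
    """The full screen layout: series definitions plus gene attributes."""

    series: list[ScreenSeries]
    genes: list[GeneSpec]

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_combo: set[tuple[Mutagen, Background]] = set()
        for s in self.series:
            if s.series_id in seen_ids:
                raise ScreenTableError(f"duplicate series_id {s.series_id!r}")
            combo = (s.mutagen, s.background)
            if combo in seen_combo:
                raise ScreenTableError(
                    f"duplicate (mutagen, background) combination "
                    f"({s.mutagen.value}, {s.background.value})"
                )
            seen_ids.add(s.series_id)
            seen_combo.add(combo)
        gene_ids = [g.gene_id for g in self.genes]
        if len(gene_ids) != len(set(gene_ids)):
            raise ScreenTableError("duplicate gene_id in design")
        self._series_by_id = {s.series_id: s for s in self.series}
        self._gene_by_id = {g.gene_id: g for g in self.genes}

    # -- lookups ---------------------------------------------------------
    def get_series(self, series_id: str) -> ScreenSeries:
        try:
            return self._series_by_id[series_id]
        except KeyError:
            raise ScreenTableError(f"unknown series_id {series_id!r}") from None

    def get_gene(self, gene_id: str) -> GeneSpec:
        try:
            return self._gene_by_id[gene_id]
        except KeyError:
            raise ScreenTableError(f"unknown gene_id {gene_id!r}") from None

    @property
    def series_ids(self) -> list[str]:
        return [s.series_id for s in self.series]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def is_eligible(self, gene_id: str, series_id: str) -> bool:
        """True if an allele of ``gene_id`` can be isolated in ``series_id``."""
        return self.get_gene(gene_id).eligible_in(self.get_series(series_id).background)

    def eligible_series(
        self,
        gene_id: str,
        mutagen: Mutagen | None = None,
        background: Background | None = None,
    ) -> list[ScreenSeries]:
        """Series in which the gene is isolable, optionally filtered."""
        gene = self.get_gene(gene_id)
        out = []
        for s in self.series:
            if mutagen is not None and s.mutagen is not mutagen:
                continue
            if background is not None and s.background is not background:
                continue
            if gene.eligible_in(s.background):
                out.append(s)
        return out

    @property
    def total_haploid_genomes(self) -> int:
        return sum(s.haploid_genomes for s in self.series)


@dataclass
class AlleleTable:
    """Allele counts per (gene, series); missing pairs count as zero."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def count(self, gene_id: str, series_id: str) -> int:
        return self.counts.get((gene_id, series_id), 0)

    def set_count(self, gene_id: str, series_id: str, count: int) -> None:
        self.counts[(gene_id, series_id)] = int(count)

    def gene_total(self, gene_id: str, series_ids: Iterable[str] | None = None) -> int:
        if series_ids is None:
            return sum(c for (g, _), c in self.counts.items() if g == gene_id)
        sel = set(series_ids)
        return sum(c for (g, s), c in self.counts.items() if g == gene_id and s in sel)

    def total(self) -> int:
        return sum(self.counts.values())

    def per_gene_counts(
        self, gene_ids: Iterable[str], series_ids: Iterable[str] | None = None
    ) -> dict[str, int]:
        """Summed counts per gene over a series selection (zeros included)."""
        return {g: self.gene_total(g, series_ids) for g in gene_ids}


@dataclass(frozen=True)
class Violation:
    rule: str
    subject: str
    message: str


@dataclass
class ValidationReport:
    errors: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# TSV I/O


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_bool(value: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ParseError(f"{where}: cannot parse boolean value {value!r}")


def _parse_genomes(value: str, where: str) -> int:
    try:
        x = float(str(value))
    except (TypeError, ValueError):
        raise ParseError(f"{where}: non-numeric haploid genome count {value!r}") from None
    n = round(x)
    if abs(x - n) > 1e-6 * max(1.0, abs(x)):
        raise ParseError(f"{where}: haploid genome count {value!r} is not an integer")
    return int(n)


def _parse_enum(cls, value: str, where: str):
    try:
        return cls(str(value).strip())
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise ParseError(f"{where}: unknown {cls.__name__} {value!r} (expected one of {valid})") from None


def read_design(series_path: str | Path, genes_path: str | Path) -> ScreenDesign:
    """Read a screen design from its two TSV files.

    ``series_path`` columns: series_id, mutagen, background, haploid_genomes.
    ``genes_path`` columns: gene_id, linkage, bypassed_by_transgene,
    suppressed_by_acs22, temperature_sensitive, n_loci.
    """
    sdf = _read_tsv(series_path, ["series_id", "mutagen", "background", "haploid_genomes"])
    series = []
    for i, row in sdf.iterrows():
        where = f"{series_path} row {i + 2} ({row['series_id']})"
        series.append(
            ScreenSeries(
                series_id=str(row["series_id"]).strip(),
                mutagen=_parse_enum(Mutagen, row["mutagen"], where),
                background=_parse_enum(Background, row["background"], where),
                haploid_genomes=_parse_genomes(row["haploid_genomes"], where),
            )
        )
    gdf = _read_tsv(
        genes_path,
        ["gene_id", "linkage", "bypassed_by_transgene", "suppressed_by_acs22",
         "temperature_sensitive", "n_loci"],
    )
    genes = []
    for i, row in gdf.iterrows():
        where = f"{genes_path} row {i + 2} ({row['gene_id']})"
        try:
            n_loci = int(row["n_loci"])
        except (TypeError, ValueError):
            raise ParseError(f"{where}: non-integer n_loci {row['n_loci']!r}") from None
        genes.append(
            GeneSpec(
                gene_id=str(row["gene_id"]).strip(),
                linkage=str(row["linkage"]).strip(),
                bypassed_by_transgene=_parse_bool(row["bypassed_by_transgene"], where),
                suppressed_by_acs22=_parse_bool(row["suppressed_by_acs22"], where),
                temperature_sensitive=_parse_bool(row["temperature_sensitive"], where),
                n_loci=n_loci,
            )
        )
    if not series:
        raise ParseError(f"{series_path}: no series defined")
    return ScreenDesign(series=series, genes=genes)


def read_allele_table(
    path: str | Path, design: ScreenDesign, strict: bool = True
) -> AlleleTable:
    """Read a long-format allele table (gene_id, series_id, count).

    With ``strict`` (default) a positive count in a cell the design marks
    ineligible raises ``ScreenTableError`` ("impossible isolation"); use
    :func:`validate` for a non-throwing report.
    """
    df = _read_tsv(path, ["gene_id", "series_id", "count"])
    table = AlleleTable()
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        gene_id = str(row["gene_id"]).strip()
        series_id = str(row["series_id"]).strip()
        design.get_gene(gene_id)
        design.get_series(series_id)
        try:
            count = int(row["count"])
        except (TypeError, ValueError):
            raise ParseError(f"{where}: non-integer count {row['count']!r}") from None
        if (gene_id, series_id) in table.counts:
            raise ParseError(f"{where}: duplicate entry for ({gene_id}, {series_id})")
        table.set_count(gene_id, series_id, count)
    if strict:
        report = validate(table, design)
        if not report.ok:
            msgs = "; ".join(v.message for v in report.errors)
            raise ScreenTableError(f"{path}: {msgs}")
    return table


def validate(table: AlleleTable, design: ScreenDesign) -> ValidationReport:
    """Check an allele table against its design; violations are reported,
    never thrown."""
    report = ValidationReport()
    for (gene_id, series_id), count in sorted(table.counts.items()):
        subject = f"({gene_id}, {series_id})"
        if gene_id not in design._gene_by_id:
            report.errors.append(Violation("unknown-gene", subject, f"unknown gene {gene_id!r}"))
            continue
        if series_id not in design._series_by_id:
            report.errors.append(Violation("unknown-series", subject, f"unknown series {series_id!r}"))
            continue
        if count < 0:
            report.errors.append(
                Violation("negative-count", subject, f"negative count {count} for {subject}")
            )
        if count > 0 and not design.is_eligible(gene_id, series_id):
            report.errors.append(
                Violation(
                    "impossible-isolation",
                    subject,
                    f"impossible isolation: {count} allele(s) of {gene_id} in "
                    f"ineligible series {series_id}",
                )
            )
    for gene in design.genes:
        if table.gene_total(gene.gene_id) == 0:
            report.warnings.append(
                Violation("zero-gene", gene.gene_id, f"gene {gene.gene_id} has no alleles")
            )
    return report


def write_design(design: ScreenDesign, series_path: str | Path, genes_path: str | Path) -> None:
    sdf = pd.DataFrame(
        [
            {
                "series_id": s.series_id,
                "mutagen": s.mutagen.value,
                "background": s.background.value,
                "haploid_genomes": s.haploid_genomes,
            }
            for s in design.series
        ]
    )
    sdf.to_csv(series_path, sep="\t", index=False)
    gdf = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "linkage": g.linkage,
                "bypassed_by_transgene": str(g.bypassed_by_transgene).lower(),
                "suppressed_by_acs22": str(g.suppressed_by_acs22).lower(),
                "temperature_sensitive": str(g.temperature_sensitive).lower(),
                "n_loci": g.n_loci,
            }
            for g in design.genes
        ]
    )
    gdf.to_csv(genes_path, sep="\t", index=False)


def write_allele_table(table: AlleleTable, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "series_id": s, "count": c}
        for (g, s), c in sorted(table.counts.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "series_id", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Packaged reference fixtures (the published screen's Tables)


def _data_path(name: str):
    return resources.files("satscreen.data").joinpath(name)


def load_reference_design() -> ScreenDesign:
    """The packaged six-series, thirteen-gene reference screen design."""
    with resources.as_file(_data_path("series.tsv")) as sp, resources.as_file(
        _data_path("genes.tsv")
    ) as gp:
        return read_design(sp, gp)


def load_reference_allele_table(design: ScreenDesign | None = None) -> AlleleTable:
    """The packaged reference allele table (118 alleles over 13 groups)."""
    if design is None:
        design = load_reference_design()
    with resources.as_file(_data_path("alleles.tsv")) as ap:
        return read_allele_table(ap, design)
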