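"""Mutagen mutation-spectrum classification and the paired mutagen test.

Sequenced mutation sites are classified into the six base-pair substitution
classes plus indels.  A substitution reported on either strand is
canonicalized to the class named with the purine on the reference side of
the pair (C>T on the minus strand is the complement of G>A, hence GC>AT):
the class is a property of the base *pair*, not of the reported strand.

EMS alkylates guanine and produces almost exclusively GC>AT transitions;
ENU has a broader spectrum including AT-pair changes and small indels.
The per-gene mutagen efficiency comparison is a paired two-sample t-test
on per-gene (EMS - ENU) allele-frequency differences.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import ttest_rel

from ._display import ratio_display
from .frequency import FrequencyTable, UndefinedCellError
from .tables import Mutagen, ParseError, ScreenTableError

__all__ = [
    "Strand",
    "MutationKind",
    "MutationRecord",
    "SpectrumTable",
    "SUBSTITUTION_CLASSES",
    "CLASSES",
    "classify_change",
    "spectrum_table",
    "paired_mutagen_comparison",
    "PairedComparison",
    "read_mutation_table",
    "load_reference_mutations",
]


class Strand(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"


class MutationKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INDEL = "indel"


SUBSTITUTION_CLASSES = ("GC>AT", "AT>GC", "GC>TA", "GC>CG", "AT>CG", "AT>TA")
CLASSES = SUBSTITUTION_CLASSES + ("indel",)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
# purine-reference substitution -> base-pair class
_PURINE_CLASS = {
    ("G", "A"): "GC>AT",
    ("A", "G"): "AT>GC",
    ("G", "T"): "GC>TA",
    ("G", "C"): "GC>CG",
    ("A", "C"): "AT>CG",
    ("A", "T"): "AT>TA",
}


@dataclass(frozen=True)
class MutationRecord:
    allele_id: str
    gene_id: str
    mutagen: Mutagen
    kind: MutationKind
    ref_base: str | None = None
    alt_base: str | None = None
    strand: Strand = Strand.PLUS

    def __post_init__(self) -> None:
        if self.kind is MutationKind.SUBSTITUTION:
            if self.ref_base not in _COMPLEMENT or self.alt_base not in _COMPLEMENT:
                raise ScreenTableError(
                    f"{self.allele_id}: substitution needs ref/alt bases in ACGT, "
                    f"got {self.ref_base!r}>{self.alt_base!r}"
                )
            if self.ref_base == self.alt_base:
                raise ScreenTableError(
                    f"{self.allele_id}: identical ref and alt base {self.ref_base!r}"
                )
        else:
            if self.ref_base or self.alt_base:
                raise ScreenTableError(
                    f"{self.allele_id}: indel records carry no ref/alt bases"
                )


def classify_change(record: MutationRecord) -> str:
    """Canonical base-pair class of one mutation record.

    Substitutions whose reference base is a pyrimidine are complemented to
    the purine-reference representation first, so the same physical change
    reported on either strand maps to the same class.
    """
    if record.kind is MutationKind.INDEL:
        return "indel"
    ref, alt = record.ref_base, record.alt_base
    if ref in ("C", "T"):  # pyrimidine reference: take the complementary strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return _PURINE_CLASS[(ref, alt)]


class SpectrumTable:
    """Per-mutagen mutation-class counts and percentages."""

    def __init__(self, counts: dict[Mutagen, dict[str, int]]):
        self._counts = counts

    def count(self, mutagen: Mutagen | str, cls: str) -> int:
        return self._counts.get(Mutagen(mutagen), {}).get(cls, 0)

    def total(self, mutagen: Mutagen | str) -> int:
        return sum(self._counts.get(Mutagen(mutagen), {}).values())

    def percentage(self, mutagen: Mutagen | str, cls: str) -> float:
        """Unrounded percentage of the class among the mutagen's records."""
        total = self.total(mutagen)
        if total == 0:
            raise ScreenTableError(f"no records for mutagen {mutagen}")
        return 100.0 * self.count(mutagen, cls) / total

    def percentage_display(self, mutagen: Mutagen | str, cls: str) -> float:
        """Percentage rounded half-to-even at one decimal."""
        total = self.total(mutagen)
        if total == 0:
            raise ScreenTableError(f"no records for mutagen {mutagen}")
        return ratio_display(self.count(mutagen, cls), total, 100, 1)

    @property
    def mutagens(self) -> list[Mutagen]:
        return sorted(self._counts, key=lambda m: m.value)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mut in self.mutagens:
            for cls in CLASSES:
                rows.append(
                    {
                        "mutagen": mut.value,
                        "class": cls,
                        "count": self.count(mut, cls),
                        "percent": self.percentage_display(mut, cls),
                    }
                )
        return pd.DataFrame(rows, columns=["mutagen", "class", "count", "percent"])

    def summary(self) -> str:
        return self.to_frame().to_string(index=False)


def spectrum_table(records: Sequence[MutationRecord]) -> SpectrumTable:
    """Tabulate class counts and percentages per mutagen."""
    if not records:
        raise ScreenTableError("empty mutation record list")
    counts: dict[Mutagen, dict[str, int]] = {}
    for rec in records:
        cls = classify_change(rec)
        per = counts.setdefault(rec.mutagen, {c: 0 for c in CLASSES})
        per[cls] += 1
    return SpectrumTable(counts)


@dataclass(frozen=True)
class PairedComparison:
    """Paired two-sample t-test of per-gene mutagen allele frequencies."""

    statistic: float
    df: int
    pvalue: float
    differences: tuple[float, ...]  # per-gene EMS - ENU, in display 1e-5 units

    def summary(self) -> str:
        return (
            f"paired two-sample t-test: t = {self.statistic:.3f}, "
            f"df = {self.df}, two-sided p = {self.pvalue:.4f}"
        )


def paired_mutagen_comparison(
    ftable: FrequencyTable,
    genes: Sequence[str],
    use_display: bool = True,
) -> PairedComparison:
    """Paired t-test of EMS vs ENU per-gene allele frequencies.

    Every listed gene must have a defined EMS cell; a missing ENU cell is
    imputed as frequency 0 (genes with no ENU-eligible series).  By default
    the test runs on the one-decimal display frequencies, i.e. the numbers
    a screen table prints; ``use_display=False`` switches to the unrounded
    frequencies (reported on the same 1e-5 scale).
    """
    if len(genes) < 2:
        raise ScreenTableError("paired comparison needs at least two genes")
    ems, enu = [], []
    for g in genes:
        cell = ftable.cell(g, "mutagen", Mutagen.EMS)  # raises if undefined
        ems.append(cell.display_1e5 if use_display else cell.freq_per_genome * 1e5)
        try:
            c = ftable.cell(g, "mutagen", Mutagen.ENU)
            enu.append(c.display_1e5 if use_display else c.freq_per_genome * 1e5)
        except UndefinedCellError:
            enu.append(0.0)
    res = ttest_rel(ems, enu)
    diffs = tuple(a - b for a, b in zip(ems, enu))
    if all(d == 0 for d in diffs):  # identical pairs: t = 0, p = 1 by convention
        return PairedComparison(0.0, len(genes) - 1, 1.0, diffs)
    return PairedComparison(
        float(res.statistic), len(genes) - 1, float(res.pvalue), diffs
    )


# ---------------------------------------------------------------------------
# TSV I/O and the packaged (synthetic) reference fixture


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read mutation records from TSV (columns: allele_id, gene_id, mutagen,
    kind, ref_base, alt_base, strand)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    required = ["allele_id", "gene_id", "mutagen", "kind", "ref_base", "alt_base", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        kind = MutationKind(str(row["kind"]).strip())
        is_sub = kind is MutationKind.SUBSTITUTION

        def base(v):
            v = None if pd.isna(v) else str(v).strip() or None
            return v

        records.append(
            MutationRecord(
                allele_id=str(row["allele_id"]).strip(),
                gene_id=str(row["gene_id"]).strip(),
                mutagen=Mutagen(str(row["mutagen"]).strip()),
                kind=kind,
                ref_base=base(row["ref_base"]) if is_sub else None,
                alt_base=base(row["alt_base"]) if is_sub else None,
                strand=Strand(str(row["strand"]).strip()),
            )
        )
    return records


def load_reference_mutations() -> list[MutationRecord]:
    """The packaged synthetic 45-site mutation fixture.

    The true site list is not published; this fixture is reconstructed from
    the published per-class percentages (13 ENU and 32 EMS records, the
    unique integer solutions) with arbitrary strand assignments.
    """
    ref = resources.files("satscreen.data").joinpath("mutations_synthetic.tsv")
    with resources.as_file(ref) as path:
        return read_mutation_table(path)
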