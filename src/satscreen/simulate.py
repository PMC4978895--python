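"""Generative model of the pooled mutagenesis screen.

The screen is simulated pool by pool: mutagenized parents are plated in
pools of F1 animals (each F1 carries two mutagenized haploid genomes), a
large synchronized F2 brood per pool is inspected for the mutant phenotype,
and **at most one isolate is kept per pool** so that every kept isolate is
an independent mutational event.  Genes are masked per series by the same
background-eligibility rules the analysis modules use.

Two detection modes:

* ``effective`` (default) — each mutant haploid genome yields a detectable
  candidate directly with probability ``f_g``, the gene's *effective*
  isolable allele frequency.  Published screen-table frequencies already
  fold in detection and survival, so reproducing observed allele counts
  from them requires ``survival_prob=1`` in this mode.
* ``mechanistic`` — carrier F1s are drawn at the mutation frequency and
  each is detected only if at least one of its scored F2 descendants is a
  phenotypic homozygote: detection probability ``1 - (3/4)**(f2/f1)`` per
  carrier.  This mode extrapolates beyond the published numbers and exists
  for screen-design exploration (pool size, F2 depth).

Randomness: a single global seed, with per-pool substreams spawned by
``(series index, pool index)`` counters so changing one series' pool count
never reshuffles another's draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .frequency import FrequencyTable
from .saturation import SaturationResult, saturation_by_series
from .tables import (
    AlleleTable,
    Background,
    GeneSpec,
    Mutagen,
    ScreenDesign,
    ScreenSeries,
    ScreenTableError,
)

__all__ = [
    "SimGene",
    "SeriesPlan",
    "SimConfig",
    "PoolRecord",
    "SimulatedScreen",
    "simulate_screen",
    "recovery_experiment",
    "RecoveryResult",
    "generate_complementation_fixture",
    "reference_testers",
    "config_from_design",
    "load_sim_config",
]

DEFAULT_F1_RANGE = (150, 200)
DEFAULT_F2_RANGE = (1500, 3000)
DEFAULT_SURVIVAL = 1.0 / 3.0


@dataclass(frozen=True)
class SimGene:
    """A gene with its per-mutagen effective isolable allele frequency
    (per mutagenized haploid genome)."""

    spec: GeneSpec
    freq: dict[Mutagen, float]

    def frequency(self, mutagen: Mutagen) -> float:
        return self.freq.get(mutagen, 0.0)


@dataclass(frozen=True)
class SeriesPlan:
    """Pool plan for one screen series."""

    series: ScreenSeries
    n_pools: int
    f1_range: tuple[int, int] = DEFAULT_F1_RANGE
    f2_range: tuple[int, int] = DEFAULT_F2_RANGE

    @property
    def nominal_genomes(self) -> float:
        lo, hi = self.f1_range
        return self.n_pools * 2 * (lo + hi) / 2.0


@dataclass
class SimConfig:
    """Full simulator configuration; validated before any sampling."""

    genes: list[SimGene]
    plans: list[SeriesPlan]
    survival_prob: float = DEFAULT_SURVIVAL
    mode: str = "effective"  # or "mechanistic"
    homozygote_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("effective", "mechanistic"):
            raise ScreenTableError(f"unknown detection mode {self.mode!r}")
        if not 0.0 <= self.survival_prob <= 1.0:
            raise ScreenTableError("survival_prob must be in [0, 1]")
        if not 0.0 < self.homozygote_fraction <= 1.0:
            raise ScreenTableError("homozygote_fraction must be in (0, 1]")
        if not self.genes:
            raise ScreenTableError("config defines no genes")
        if not self.plans:
            raise ScreenTableError("config defines no series plans")
        for g in self.genes:
            for m, f in g.freq.items():
                if not 0.0 <= f < 1.0:
                    raise ScreenTableError(
                        f"gene {g.spec.gene_id}: frequency {f} for {m} outside [0, 1)"
                    )
        for p in self.plans:
            if p.n_pools < 1:
                raise ScreenTableError(f"series {p.series.series_id}: n_pools must be >= 1")
            for name, (lo, hi) in (("f1_range", p.f1_range), ("f2_range", p.f2_range)):
                if lo < 1 or hi < lo:
                    raise ScreenTableError(
                        f"series {p.series.series_id}: degenerate {name} ({lo}, {hi})"
                    )

    @property
    def design(self) -> ScreenDesign:
        """The ScreenDesign implied by the configuration."""
        return ScreenDesign(
            series=[p.series for p in self.plans], genes=[g.spec for g in self.genes]
        )


@dataclass(frozen=True)
class PoolRecord:
    pool_id: str
    series_id: str
    haploid_genomes: int
    candidates: dict[str, int]  # gene -> surviving candidate count
    kept: str | None  # isolate id, or None


@dataclass
class SimulatedScreen:
    """Simulator output: observed allele table plus full ground truth."""

    observed: AlleleTable
    truth: dict[str, str]  # isolate id -> gene id
    pools: list[PoolRecord]
    config: SimConfig
    seed: int

    def per_gene_expected(self, keep_one_loss: bool = True) -> dict[str, float]:
        """Analytic expected kept-isolate count per gene.

        With ``keep_one_loss`` (default) the expectation accounts for the
        at-most-one-isolate-per-pool rule: in a pool of ``G`` haploid
        genomes with total surviving-candidate rate ``F`` per genome, the
        number of candidates is approximately Poisson(``G*F``) and exactly
        one is kept whenever any appear, so the expected kept count of gene
        ``g`` is ``(f_g/F) * (1 - exp(-G*F))`` per pool (averaged over the
        pool-size distribution).  The per-pool retention factor
        ``(1 - exp(-lambda))/lambda`` is ~0.93 at the reference screen's
        densest series (lambda ~ 0.15) — the loss is *not* negligible when
        many genes compete within a pool.  ``keep_one_loss=False`` returns
        the naive ``genomes x f_g x survival`` expectation (exact only in
        the sparse-candidate limit).  Effective mode only; the mechanistic
        detection thinning is not folded into this formula.
        """
        out = {g.spec.gene_id: 0.0 for g in self.config.genes}
        surv = self.config.survival_prob
        for p in self.config.plans:
            rates = {
                g.spec.gene_id: g.frequency(p.series.mutagen) * surv
                for g in self.config.genes
                if g.spec.eligible_in(p.series.background)
            }
            if not keep_one_loss:
                for gid, f in rates.items():
                    out[gid] += p.nominal_genomes * f
                continue
            F = sum(rates.values())
            if F <= 0:
                continue
            lo, hi = p.f1_range
            f1_values = np.arange(lo, hi + 1)
            # expected kept isolates per pool, any gene
            kept_per_pool = float(np.mean(1.0 - np.exp(-2.0 * f1_values * F)))
            for gid, f in rates.items():
                out[gid] += p.n_pools * kept_per_pool * f / F
        return out

    def summary(self) -> pd.DataFrame:
        expected = self.per_gene_expected()
        rows = [
            {
                "gene_id": g.spec.gene_id,
                "expected": expected[g.spec.gene_id],
                "observed": self.observed.gene_total(g.spec.gene_id),
            }
            for g in self.config.genes
        ]
        return pd.DataFrame(rows, columns=["gene_id", "expected", "observed"])


def _pool_rng(seed: int, series_idx: int, pool_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(series_idx, pool_idx))
    )


def simulate_screen(
    config: SimConfig, seed: int | None = None, log_pools: bool = True
) -> SimulatedScreen:
    """Run one full simulated screen; identical (config, seed) gives
    identical output."""
    if seed is None:
        seed = config.seed
    gene_ids = [g.spec.gene_id for g in config.genes]
    observed = AlleleTable()
    truth: dict[str, str] = {}
    pools: list[PoolRecord] = []

    for series_idx, plan in enumerate(config.plans):
        series = plan.series
        fvec = np.array(
            [
                g.frequency(series.mutagen) if g.spec.eligible_in(series.background) else 0.0
                for g in config.genes
            ]
        )
        f1_lo, f1_hi = plan.f1_range
        f2_lo, f2_hi = plan.f2_range
        for pool_idx in range(plan.n_pools):
            rng = _pool_rng(seed, series_idx, pool_idx)
            f1 = int(rng.integers(f1_lo, f1_hi + 1))
            genomes = 2 * f1
            carriers = rng.binomial(genomes, fvec)
            if config.mode == "mechanistic":
                f2 = int(rng.integers(f2_lo, f2_hi + 1))
                p_detect = 1.0 - (1.0 - config.homozygote_fraction) ** (f2 / f1)
                candidates = rng.binomial(carriers, p_detect)
            else:
                candidates = carriers
            if config.survival_prob < 1.0:
                survivors = rng.binomial(candidates, config.survival_prob)
            else:
                survivors = candidates
            total = int(survivors.sum())
            kept = None
            if total > 0:
                cum = np.cumsum(survivors)
                gi = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                gene_id = gene_ids[gi]
                kept = f"{series.series_id}:p{pool_idx:04d}"
                observed.set_count(
                    gene_id, series.series_id, observed.count(gene_id, series.series_id) + 1
                )
                truth[kept] = gene_id
            if log_pools:
                pools.append(
                    PoolRecord(
                        pool_id=f"{series.series_id}:p{pool_idx:04d}",
                        series_id=series.series_id,
                        haploid_genomes=genomes,
                        candidates={
                            gid: int(c) for gid, c in zip(gene_ids, survivors) if c > 0
                        },
                        kept=kept,
                    )
                )
    return SimulatedScreen(observed=observed, truth=truth, pools=pools, config=config, seed=seed)


@dataclass
class RecoveryResult:
    """Replicate distribution of the saturation estimator on simulated
    screens, with per-gene count calibration."""

    n_reps: int
    selection: tuple[str, ...]
    per_gene: pd.DataFrame  # gene_id, expected_naive, expected, mean_observed, sd, se
    N: np.ndarray
    lambda_: np.ndarray
    N0: np.ndarray
    all_found_fraction: float

    @property
    def all_found_se(self) -> float:
        p = self.all_found_fraction
        return math.sqrt(p * (1 - p) / self.n_reps)

    def summary(self) -> str:
        lines = [
            f"recovery experiment: {self.n_reps} replicates, "
            f"selection {','.join(self.selection)}",
            f"mean N = {self.N.mean():.3f}, mean lambda = {self.lambda_.mean():.3f}, "
            f"mean N0 = {self.N0.mean():.4f} "
            f"(MC se {self.N0.std(ddof=1) / math.sqrt(self.n_reps):.4f})",
            f"fraction of replicates with every true gene found: "
            f"{self.all_found_fraction:.3f} +/- {self.all_found_se:.3f}",
            "",
            self.per_gene.to_string(index=False),
        ]
        return "\n".join(lines)


def recovery_experiment(
    config: SimConfig,
    n_reps: int,
    seed: int | None = None,
    selection: Sequence[str] | None = None,
) -> RecoveryResult:
    """Repeatedly simulate the screen and re-estimate saturation.

    Reports the replicate distribution of (N, lambda, N0) from
    :func:`satscreen.saturation.saturation_by_series` on the chosen series
    selection, the fraction of replicates in which every true gene yielded
    at least one kept isolate, and per-gene observed-count calibration
    against the binomial expectation.
    """
    if n_reps < 1:
        raise ScreenTableError("n_reps must be >= 1")
    if seed is None:
        seed = config.seed
    design = config.design
    if selection is None:
        selection = design.series_ids
    selection = tuple(selection)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)

    gene_ids = [g.spec.gene_id for g in config.genes]
    obs = np.zeros((n_reps, len(gene_ids)))
    Ns, lams, N0s = [], [], []
    all_found = 0
    expected = None
    expected_naive = None
    for rep in range(n_reps):
        sim = simulate_screen(config, seed=int(rep_seeds[rep]), log_pools=False)
        if expected is None:
            expected = sim.per_gene_expected(keep_one_loss=True)
            expected_naive = sim.per_gene_expected(keep_one_loss=False)
        totals = sim.observed.per_gene_counts(gene_ids)
        obs[rep] = [totals[g] for g in gene_ids]
        if all(totals[g] > 0 for g in gene_ids):
            all_found += 1
        try:
            sat = saturation_by_series(sim.observed, design, selection)
            Ns.append(sat.N)
            lams.append(sat.lambda_)
            N0s.append(sat.N0)
        except ScreenTableError:  # replicate with no alleles at all
            Ns.append(0)
            lams.append(np.nan)
            N0s.append(np.nan)
    per_gene = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expected_naive": [expected_naive[g] for g in gene_ids],
            "expected": [expected[g] for g in gene_ids],
            "mean_observed": obs.mean(axis=0),
            "sd": obs.std(axis=0, ddof=1),
            "se": obs.std(axis=0, ddof=1) / math.sqrt(n_reps),
        }
    )
    return RecoveryResult(
        n_reps=n_reps,
        selection=selection,
        per_gene=per_gene,
        N=np.array(Ns, dtype=float),
        lambda_=np.array(lams, dtype=float),
        N0=np.array(N0s, dtype=float),
        all_found_fraction=all_found / n_reps,
    )


# ---------------------------------------------------------------------------
# Complementation fixture generation


def reference_testers() -> dict[str, str]:
    """Reference-tester ids for the four previously known genes."""
    return {
        "maoc-1(ref)": "maoc-1",
        "dhs-28(ref)": "dhs-28",
        "daf-22(ref)": "daf-22",
        "prx-10(ref)": "prx-10",
    }


def generate_complementation_fixture(
    table: AlleleTable,
    testers: Mapping[str, str] | None = None,
    design: str = "incremental",
    seed: int = 0,
):
    """Generate isolates and pairwise complementation tests from an allele
    table's ground truth (one isolate per allele).

    ``incremental`` mirrors sorting practice: each isolate is tested against
    every reference tester, then against one representative per previously
    formed novel group until it fails to complement (or founds a new group).
    ``full`` emits every isolate pair (plus all isolate-vs-tester tests when
    testers are given).

    Returns ``(isolates, tests)``; pass the same ``testers`` mapping to
    :func:`satscreen.complementation.assemble_groups`.
    """
    from .complementation import ComplementationTest

    if design not in ("incremental", "full"):
        raise ScreenTableError(f"unknown test design {design!r}")
    testers = dict(testers or {})
    known_genes = set(testers.values())

    gene_totals: dict[str, int] = {}
    for (g, _s), c in sorted(table.counts.items()):
        gene_totals[g] = gene_totals.get(g, 0) + c
    truth: dict[str, str] = {}
    isolates: list[str] = []
    for gene in sorted(gene_totals):
        for i in range(gene_totals[gene]):
            iso = f"{gene}:a{i + 1:03d}"
            isolates.append(iso)
            truth[iso] = gene

    rng = np.random.default_rng(seed)
    order = list(isolates)
    rng.shuffle(order)

    tests: list[ComplementationTest] = []
    if design == "full":
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                tests.append(ComplementationTest(a, b, truth[a] != truth[b]))
        for a in order:
            for t in sorted(testers):
                tests.append(ComplementationTest(a, t, truth[a] != testers[t]))
    else:
        novel_reps: list[str] = []  # one representative per novel group, in founding order
        for iso in order:
            gene = truth[iso]
            for t in sorted(testers):
                tests.append(ComplementationTest(iso, t, gene != testers[t]))
            if gene in known_genes:
                continue
            placed = False
            for rep in novel_reps:
                complements = truth[rep] != gene
                tests.append(ComplementationTest(iso, rep, complements))
                if not complements:
                    placed = True
                    break
            if not placed:
                novel_reps.append(iso)
    return isolates, tests


# ---------------------------------------------------------------------------
# Configuration helpers


def config_from_design(
    design: ScreenDesign,
    ftable: FrequencyTable,
    survival_prob: float = 1.0,
    mode: str = "effective",
    f1_range: tuple[int, int] = DEFAULT_F1_RANGE,
    f2_range: tuple[int, int] = DEFAULT_F2_RANGE,
    use_display: bool = True,
    seed: int = 0,
) -> SimConfig:
    """Build an effective-frequency simulator configuration that mirrors a
    real screen design.

    Per-gene per-mutagen effective frequencies are taken from the frequency
    table (display values by default, i.e. the published numbers x 1e-5);
    pool counts are chosen so the nominal genome total matches each series'
    recorded haploid genome count.
    """
    mean_f1 = (f1_range[0] + f1_range[1]) / 2.0
    plans = [
        SeriesPlan(
            series=s,
            n_pools=max(1, round(s.haploid_genomes / (2 * mean_f1))),
            f1_range=f1_range,
            f2_range=f2_range,
        )
        for s in design.series
    ]
    genes = []
    for gene in design.genes:
        freq: dict[Mutagen, float] = {}
        for m in Mutagen:
            if ftable.has_cell(gene.gene_id, "mutagen", m.value):
                c = ftable.cell(gene.gene_id, "mutagen", m.value)
                freq[m] = (c.display_1e5 * 1e-5) if use_display else c.freq_per_genome
            else:
                freq[m] = 0.0
        genes.append(SimGene(spec=gene, freq=freq))
    return SimConfig(
        genes=genes, plans=plans, survival_prob=survival_prob, mode=mode, seed=seed
    )


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a simulator configuration from YAML.

    Top-level keys: ``series`` (list of series with optional n_pools,
    f1_range, f2_range), ``genes`` (list with per-mutagen ``freq``),
    ``survival_prob``, ``mode``, ``homozygote_fraction``, ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScreenTableError(f"{path}: expected a mapping at top level")
    plans = []
    for s in raw.get("series", []):
        series = ScreenSeries(
            series_id=str(s["series_id"]),
            mutagen=Mutagen(s["mutagen"]),
            background=Background(s["background"]),
            haploid_genomes=int(float(s["haploid_genomes"])),
        )
        f1r = tuple(s.get("f1_range", DEFAULT_F1_RANGE))
        f2r = tuple(s.get("f2_range", DEFAULT_F2_RANGE))
        mean_f1 = (f1r[0] + f1r[1]) / 2.0
        n_pools = int(s.get("n_pools", max(1, round(series.haploid_genomes / (2 * mean_f1)))))
        plans.append(SeriesPlan(series=series, n_pools=n_pools, f1_range=f1r, f2_range=f2r))
    genes = []
    for g in raw.get("genes", []):
        spec = GeneSpec(
            gene_id=str(g["gene_id"]),
            linkage=str(g.get("linkage", "unknown")),
            bypassed_by_transgene=bool(g.get("bypassed_by_transgene", False)),
            suppressed_by_acs22=bool(g.get("suppressed_by_acs22", False)),
            temperature_sensitive=bool(g.get("temperature_sensitive", False)),
            n_loci=int(g.get("n_loci", 1)),
        )
        freq = {Mutagen(m): float(f) for m, f in (g.get("freq") or {}).items()}
        genes.append(SimGene(spec=spec, freq=freq))
    return SimConfig(
        genes=genes,
        plans=plans,
        survival_prob=float(raw.get("survival_prob", DEFAULT_SURVIVAL)),
        mode=str(raw.get("mode", "effective")),
        homozygote_fraction=float(raw.get("homozygote_fraction", 0.25)),
        seed=int(raw.get("seed", 0)),
    )
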