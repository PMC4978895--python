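# Methods

This note records the statistical conventions, modelling assumptions and
design choices behind satscreen, in the order a user meets them.

## Screen model and eligibility

A screen *series* is one mutagen (EMS or ENU) applied in one genetic
background (wild type, rescue-transgene, or *acs-22* null), with a recorded
number of mutagenized haploid genomes. Genes carry two boolean
eligibility attributes rather than hard-coded names, so the machinery
generalizes to other screens:

* `bypassed_by_transgene` — the rescue transgene supplies wild-type copies,
  so new mutants of the gene cannot be recognized in that background;
* `suppressed_by_acs22` — the gene's mutant phenotype requires the
  ACS-22/DGAT-2 pathway, so it cannot be isolated in the suppressor null.

Eligibility drives two things: validation (a positive count in an
ineligible cell is an "impossible isolation" error) and frequency
denominators (below). One group in the reference screen is a two-locus
mutant; it is carried as a single complementation group with `n_loci = 2`,
matching how the screen's own tallies count it.

## Allele frequencies

The frequency of gene *g* along an axis key (a mutagen or a background) is

    f = (alleles of g in contributing series) / (haploid genomes of contributing series)

where a series contributes only if its background permits isolation of *g*.
For the reference screen this yields the three published denominator rules:
WT-only (118 000 or 245 000) for bypassed-and-suppressed genes,
WT + rescue (213 000 / 159 000) for suppressed genes, and all three
backgrounds (362 000 / 308 000) for unrestricted genes.

**Three cell states.** Ineligible cells are *undefined* (written `NA`),
distinct from eligible cells with zero alleles (frequency `0.0`). Both
round-trip through the TSV output.

**Rounding and totals.** Display values are in 10⁻⁵-per-genome units,
rounded half-to-even at one decimal through exact rational arithmetic
(`decimal`/`fractions`), so true ties such as 93.75 are not perturbed by
binary floating point. Column totals are sums of the *rounded* per-gene
display values — the only convention under which the published totals
(43.5, 28.5, 16.5, 9.0 × 10⁻⁵) reproduce exactly. Internal computation
always keeps the unrounded values.

**Known print discrepancy.** The reference table's drop-8 ENU cell prints
0.8 × 10⁻⁵ where its own footnote arithmetic (1 allele / 308 000) gives
0.3 × 10⁻⁵, exactly as the identically-sourced drop-4 cell prints. We
compute 0.3; consequently our ENU column total is 22.0 rather than the
printed 22.5. The `reproduce` report marks this as a documented deviation.

## Saturation (Poisson zero class)

With per-gene allele counts modelled as Poisson(λ),
P(κ) = λ^κ e^(−λ)/κ!; the zero class P(0) = e^(−λ) is the probability a
mutable gene yielded no allele, and N(0) = N·P(0)/(1−P(0)) converts it to
an expected count of missed genes given N identified ones.

* λ is the *observed* mean: total alleles ÷ genes with ≥ 1 allele. This is
  a zero-truncated mean and overstates the true Poisson rate by the factor
  λ/(1−e^(−λ)) — at λ = 1 the estimator converges to 1.58. The bias is a
  deliberate fidelity choice (it is the screen-genetics convention) and is
  demonstrated, not corrected, in the test suite. At the reference screen's
  λ ≥ 3.5 the factor is < 1.03 and immaterial.
* P(0) and N(0) are always computed from the **unrounded** λ
  (e^(−5.625) = 0.0036, where e^(−5.6) would give 0.0037).
* Display precision follows the reference tables: λ to one decimal, P(0)
  to four, N(0) to three. Two consequences: the pooled-series λ = 118/13 =
  9.077 displays as 9.1 where the reference prints 9.0, and the ENU/WT
  N(0) = 0.2026 displays as 0.203 where the reference prints 0.202 (that
  value appears to have been computed from the already-rounded P(0)). We
  do not emulate either; both sit within one unit of the last printed
  digit.

Alternative richness estimators (Chao1, coverage-based) are out of scope;
the Poisson zero class is the method under study.

## Complementation groups

Groups are connected components of the fails-to-complement graph, not
cliques: real test designs are incremental, and an untested pair inside a
component is uninformative, never evidence of complementation. Three
anomaly classes are always reported: a tested pair that complements inside
one component (transitivity violation), a pair tested twice with
conflicting outcomes (merged conservatively as fail-to-complement), and a
component containing two different reference testers (labels are never
silently fused). Novel groups are numbered by decreasing allele count,
ties broken by lexicographically smallest member, which makes numbering
invariant to input order.

The packaged 118-isolate fixture is *generated* from the allele table's
ground truth. The real pairwise design among the 73 unassigned mutants is
not recorded; the generator defaults to an incremental design (each
isolate against the four testers, then one representative per existing
novel group) with a full-matrix option.

## Segregation calls

Locus count compares Binomial(n, 1/4) vs Binomial(n, 1/16) log-likelihoods
at the observed count; ties favour the single-locus (more parsimonious)
model. The decision is equivalent to a single monotone threshold in k for
each n (the log-likelihood ratio is linear in k), verified against a
brute-force oracle for all n ≤ 500.

Dependence compares a 3/4 model against an all-affected model. Since the
ratio-1 model assigns zero likelihood to any unaffected progeny, k = n
forces "independent"; otherwise the 3/4 model is retained unless an exact
binomial test rejects it at α (default 0.05), giving "inconclusive".

Exact two-sided p-values use the minimum-likelihood convention: the sum of
all outcome probabilities ≤ that of the observed outcome (scipy
`binomtest` default); conventions differ between packages, so this is
stated explicitly. Calls with n below a configurable minimum (default 20)
carry a low-information flag rather than being refused.

## Mutation spectra

Substitutions are canonicalized to the base-pair class keyed by the purine
on the reference side (reported C>T on either strand ≡ G>A ≡ GC>AT); all
six substitution classes plus indel are always carried, with zeros for
unobserved classes. Percentages round half-to-even at one decimal; the
EMS GC>AT fraction is exactly 30/32 = 93.75%, displaying as 93.8 where the
reference prints the truncated 93.7 (within the ±0.1 comparison band).

The packaged mutation-site table is a **synthetic reconstruction**
(`mutations_synthetic.tsv`): the true 45-site list is unpublished, but the
printed class percentages identify the per-mutagen totals uniquely
(7.7% ≈ 1/13 → 13 ENU records; 3.1% ≈ 1/32 → 32 EMS records) and the class
counts follow (ENU 8/1/1/2/1, EMS 30/1/1). The totals coincide exactly
with the mutagen split of the 45 alleles of the four sequenced genes, so
gene assignments follow that split; strands alternate to exercise
canonicalization.

The paired mutagen comparison is a paired two-sample t-test on per-gene
(EMS − ENU) frequency differences, df = n − 1. It runs by default on the
one-decimal display frequencies — the numbers a screen table prints — with
an unrounded option. On the nine genes with an EMS frequency it gives
t = 2.23, df = 8, p = 0.057, the borderline significance the screen
reported.

## Simulator

Each pool draws an F1 count uniformly from its range (default 150–200; two
mutagenized haploid genomes per F1), per-gene candidate counts
Binomial(genomes, f_g) under the series' eligibility mask, optional
survival thinning (default 1/3), and keeps **at most one** surviving
candidate per pool, chosen uniformly — every kept isolate is an
independent mutational event.

* *Effective mode* (default): f_g is the effective isolable allele
  frequency, which already folds in detection and survival as published
  frequencies do; reproducing observed allele counts from published
  frequencies therefore uses `survival_prob = 1`.
* *Mechanistic mode*: carriers are detected with probability
  1 − (3/4)^(F2 screened per F1), for exploring pool size and F2 depth.
  This extrapolates beyond anything the reference screen reports.

**Keep-one loss.** The single-isolate rule discards candidates whenever
several co-occur in a pool. With per-pool total candidate rate
Λ = genomes × Σf_g, retention is (1 − e^(−Λ))/Λ and the expected kept
count of gene g per pool is (f_g/ΣF)(1 − e^(−Λ)). This matters: at the
reference screen's EMS/WT series Λ ≈ 0.15, a ~7% loss — the naive
`genomes × f_g` expectation is only adequate in the sparse regime
(per-gene f ~ 10⁻⁵, loss < 1%). `per_gene_expected()` returns the
corrected expectation by default, and the calibration tests hold the
500-replicate mean to within 2 Monte-Carlo standard errors of it (a few
tenths of an allele for the largest genes), while demonstrating that the
naive value overshoots the dense series by exactly the predicted loss.
The real screen was subject to the same loss, so its published effective
frequencies are net of it; simulating from them and re-applying the rule
slightly double-counts the loss — acceptable for estimator validation,
which only needs the generative process to be internally consistent.

Randomness uses one global seed with per-pool substreams spawned from
`(series index, pool index)`, so changing one series' pool count never
reshuffles another's draws; replicate seeds derive from the global seed.

What the simulator does **not** model: mutagen dose–response, linkage
between loci, balancers, temperature-regimen biology of ts alleles (the
flag is a pass-through label), clonal or maternal-effect complications,
and per-pool candidate multiplicity beyond the uniform keep-one rule
(which is an assumption; the reference screen does not report pool
multiplicities). Passing recovery tests therefore show the estimators are
calibrated for the stated sampling process, not that real screens lack
additional structure.

## Problem sizes

Everything except the simulator is desk-scale (≤ 13 genes, ≤ 118 isolates,
n ≤ 500 sweeps) and runs in well under a second per analysis. The
simulator calibration uses 500 replicates of the full six-series screen
(~1900 pools each, ~30 s total) plus a 60-screen pool for frequency
recovery — sizes chosen so Monte-Carlo standard errors are a few percent
of the quantities under test.
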