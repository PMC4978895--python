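"""Mendelian segregation inference from affected-progeny counts.

Two inferences, both on a count ``k`` of affected progeny out of ``n``
scored:

* **Locus count** — a recessive mutant segregating from a heterozygous
  parent yields 1/4 affected F2 progeny for a single locus but 1/16 for two
  unlinked recessive loci that are jointly required.  The call is the
  maximum-binomial-likelihood model; exact binomial p-values against each
  candidate fraction are supplementary diagnostics.

* **Pathway dependence** — in a cross of a recessive mutant into a
  suppressor null, F3 broods from doubly heterozygous F2 parents segregate
  3/4 affected if the suppressor rescues the mutant phenotype (the
  suppressed quarter is the suppressor-homozygote class) but 100% affected
  if the mutant is independent of the pathway.  Observing ``k = n`` forces
  the ratio-1 model (any miss has likelihood zero under it); otherwise the
  3/4 model is accepted unless rejected by an exact binomial test.

Exact two-sided p-values use the minimum-likelihood ("minlike") convention:
the sum of all outcome probabilities no larger than that of the observed
outcome (scipy's ``binomtest`` default).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

from scipy.stats import binomtest

from .tables import ScreenTableError

__all__ = ["SegregationCall", "infer_locus_count", "infer_dependence"]

DEFAULT_MIN_N = 20  # below this, calls are flagged low-information


def _binom_loglik(k: int, n: int, p: float) -> float:
    """Binomial log-likelihood log C(n,k) + k log p + (n-k) log(1-p)."""
    if p <= 0.0 or p >= 1.0:
        # degenerate models: all-or-nothing
        if p >= 1.0:
            return 0.0 if k == n else -math.inf
        return 0.0 if k == 0 else -math.inf
    comb = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    return comb + k * math.log(p) + (n - k) * math.log(1.0 - p)


@dataclass
class SegregationCall:
    """Result of a segregation-ratio model comparison.

    ``model_probs`` maps model names to their Mendelian fractions;
    ``log_likelihoods`` holds the binomial log-likelihood of the data under
    each; ``call`` is the decision and ``delta_loglik`` the winner's margin
    over the runner-up.  ``exact_test_p`` (computed lazily) holds the
    two-sided exact binomial p-value against each model's fraction.
    """

    k: int
    n: int
    model_probs: dict[str, float]
    log_likelihoods: dict[str, float]
    call: str
    delta_loglik: float
    low_information: bool = False
    alpha: float | None = None

    @cached_property
    def exact_test_p(self) -> dict[str, float]:
        out = {}
        for name, p in self.model_probs.items():
            if p >= 1.0:
                out[name] = 1.0 if self.k == self.n else 0.0
            elif p <= 0.0:
                out[name] = 1.0 if self.k == 0 else 0.0
            else:
                out[name] = binomtest(self.k, self.n, p, alternative="two-sided").pvalue
        return out

    def summary(self) -> str:
        lines = [
            "Segregation-ratio model comparison",
            "=" * 50,
            f"{'affected / total':<26}{self.k} / {self.n}  "
            f"(fraction {self.k / self.n:.4f})",
        ]
        for name, p in self.model_probs.items():
            ll = self.log_likelihoods[name]
            pv = self.exact_test_p[name]
            lines.append(
                f"  model {name:<16} p={p:<8.4g} loglik={ll:>10.3f} exact-p={pv:.4g}"
            )
        lines.append(f"{'call':<26}{self.call}")
        lines.append(f"{'delta log-likelihood':<26}{self.delta_loglik:.3f}")
        if self.low_information:
            lines.append("flag: low information (n below the configured minimum)")
        lines.append("=" * 50)
        return "\n".join(lines)


def infer_locus_count(k: int, n: int, min_n: int = DEFAULT_MIN_N) -> SegregationCall:
    """Call one vs two unlinked recessive loci from an F2 segregation count.

    Compares Binomial(n, 1/4) against Binomial(n, 1/16) likelihoods at
    ``k``; the call is the maximizer (ties favour the single-locus model,
    the more parsimonious genetics).
    """
    if n < 1:
        raise ScreenTableError("total progeny count n must be >= 1")
    if not 0 <= k <= n:
        raise ScreenTableError(f"affected count k={k} outside [0, n={n}]")
    models = {"1 locus": 1 / 4, "2 loci": 1 / 16}
    lls = {name: _binom_loglik(k, n, p) for name, p in models.items()}
    call = "1 locus" if lls["1 locus"] >= lls["2 loci"] else "2 loci"
    runner = "2 loci" if call == "1 locus" else "1 locus"
    return SegregationCall(
        k=k,
        n=n,
        model_probs=models,
        log_likelihoods=lls,
        call=call,
        delta_loglik=lls[call] - lls[runner],
        low_information=n < min_n,
    )


def infer_dependence(
    k_supersized: int, n_total: int, alpha: float = 0.05, min_n: int = DEFAULT_MIN_N
) -> SegregationCall:
    """Call pathway dependence from an F3 affected-progeny ratio.

    ``dependent`` model: affected fraction 3/4 (the suppressor-homozygote
    quarter is rescued).  ``independent`` model: fraction 1.  ``k = n``
    forces the independent call; otherwise the dependent call stands unless
    an exact binomial test rejects 3/4 at level ``alpha``, in which case the
    call is ``inconclusive``.
    """
    k, n = k_supersized, n_total
    if n < 1:
        raise ScreenTableError("total progeny count n must be >= 1")
    if not 0 <= k <= n:
        raise ScreenTableError(f"affected count k={k} outside [0, n={n}]")
    models = {"dependent": 3 / 4, "independent": 1.0}
    lls = {name: _binom_loglik(k, n, p) for name, p in models.items()}
    if k == n:
        call = "independent"
        delta = lls["independent"] - lls["dependent"]
    else:
        pval = binomtest(k, n, 3 / 4, alternative="two-sided").pvalue
        call = "dependent" if pval >= alpha else "inconclusive"
        delta = lls["dependent"] - lls["independent"]  # independent is -inf here
    return SegregationCall(
        k=k,
        n=n,
        model_probs=models,
        log_likelihoods=lls,
        call=call,
        delta_loglik=delta,
        low_information=n < min_n,
        alpha=alpha,
    )
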