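"""Analytic segregation probability layer.

With independent, fair retention of one homolog per chromosome pair, the
chance that an embryo keeps the homolog of one pre-specified parental origin
at every one of n pairs is 2^-n — the classical semi-cloning odds, vanishingly
small for the mouse's 20 pairs. The number of properly segregated chromosomes
per embryo is binomial in the per-pair nondisjunction rate, which can be
inverted from cohort counts with an exact (Clopper–Pearson) interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MOUSE_CHROMOSOME_PAIRS = 20


@dataclass(frozen=True)
class SegregationModelParams:
    n_pairs_of_chromosomes: int = MOUSE_CHROMOSOME_PAIRS
    p_proper: float = 1.0
    p_ndj_to_ppb: float = 0.5

    def __post_init__(self):
        if self.n_pairs_of_chromosomes < 0:
            raise ValueError("n_pairs_of_chromosomes must be >= 0")
        for name in ("p_proper", "p_ndj_to_ppb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")


def semicloning_probability(
    n: int, p_proper: float = 1.0, either_parent: bool = False
) -> float:
    """Probability that all n chromosome pairs segregate properly AND the
    embryo retains the homolog of one pre-specified parental origin each time.

    Equals ``(p_proper/2)**n``; strictly below 2^-n whenever segregation is
    imperfect. With ``either_parent=True`` the event is "all retained homologs
    share *some* single parental origin" (twice the probability for n >= 1).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= p_proper <= 1.0:
        raise ValueError("p_proper must lie in [0,1]")
    p = (p_proper / 2.0) ** n
    if either_parent and n >= 1:
        p *= 2.0
    return float(p)


def proper_count_distribution(n: int, p_ndj: float) -> np.ndarray:
    """Binomial(n, 1 - p_ndj) pmf over 0..n properly segregated chromosomes."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= p_ndj <= 1.0:
        raise ValueError("p_ndj must lie in [0,1]")
    return stats.binom.pmf(np.arange(n + 1), n, 1.0 - p_ndj)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class NdjEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    n_proper: int
    n_classified: int
    level: float


def estimate_ndj_rate(summary_or_proper, n_classified: int | None = None, level: float = 0.95) -> NdjEstimate:
    """Estimate the per-chromosome nondisjunction rate from cohort counts.

    Accepts either a :class:`~haplotrace.segregation.SegregationSummary` (its
    ``total_proper``/``total_classified``, i.e. AMBIGUOUS chromosomes excluded
    from the denominator) or the two totals directly. p_hat = 1 - proper /
    classified, with an exact Clopper–Pearson interval on the nondisjunction
    proportion.
    """
    if n_classified is None:
        summary = summary_or_proper
        n_proper = int(summary.total_proper)
        n_classified = int(summary.total_classified)
    else:
        n_proper = int(summary_or_proper)
        n_classified = int(n_classified)
    if n_classified <= 0:
        raise ValueError("no classified chromosomes: cannot estimate the rate")
    if not 0 <= n_proper <= n_classified:
        raise ValueError("need 0 <= proper <= classified")
    k_ndj = n_classified - n_proper
    lo, hi = clopper_pearson(k_ndj, n_classified, level)
    return NdjEstimate(
        p_hat=k_ndj / n_classified,
        ci_low=lo,
        ci_high=hi,
        n_proper=n_proper,
        n_classified=n_classified,
        level=level,
    )
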