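"""Exact combinatorial statistics for drug- and gene-set enrichment.

This module is the numerical kernel shared by the enrichment analyses:
a two-sided Fisher exact test on 2x2 contingency tables, the upper tail
of the hypergeometric distribution for gene-set overlap, Benjamini-
Hochberg adjustment, and a two-sided Wilcoxon rank-sum comparison.

All tail sums are accumulated in log space from log-gamma binomial
coefficients so that p-values far below double-precision underflow of a
naive product (the enrichment tables here reach ~1e-26) are still exact
to full relative precision.  A p-value of exactly zero is never
reported: if the log-space sum underflows even the subnormal range, the
smallest positive float is returned and flagged (see :class:`PValue`).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "ContingencyTable2x2",
    "HypergeomQuery",
    "PValue",
    "RankSumResult",
    "fisher_exact_two_sided",
    "hypergeom_sf",
    "hypergeom_pmf",
    "benjamini_hochberg",
    "rank_sum_test",
]

#: smallest positive (subnormal) double; stand-in for an underflowed p-value
_TINY = float(np.nextafter(0.0, 1.0))

# relative guard when comparing point probabilities for the two-sided sum,
# matching the convention of R's fisher.test (relErr = 1 + 1e-7)
_REL_ERR = 1e-7


class PValue(float):
    """A p-value that remembers its log and whether it underflowed.

    Behaves as a plain ``float`` everywhere; ``log_p`` is the natural log
    computed in log space (finite even when the float value underflows to
    the subnormal range), and ``underflow`` is True when the probability
    is below the smallest positive double and the reported float is that
    smallest positive value rather than zero.
    """

    log_p: float
    underflow: bool

    def __new__(cls, log_p: float) -> "PValue":
        p = math.exp(log_p) if log_p > -745.0 else 0.0
        underflow = p <= 0.0 and log_p > -math.inf
        obj = super().__new__(cls, min(p, 1.0) if p > 0.0 else _TINY)
        obj.log_p = min(log_p, 0.0)
        obj.underflow = underflow
        return obj

    @classmethod
    def one(cls) -> "PValue":
        return cls(0.0)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one category comparison between two entity sets.

    ``n_in_a`` / ``n_in_b`` are the members of set A / set B inside the
    category; ``n_out_a`` / ``n_out_b`` are the members outside it, so
    that rows are category membership and columns are the two sets.
    """

    n_in_a: int
    n_in_b: int
    n_out_a: int
    n_out_b: int

    def __post_init__(self) -> None:
        for name in ("n_in_a", "n_in_b", "n_out_a", "n_out_b"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def size_a(self) -> int:
        return self.n_in_a + self.n_out_a

    @property
    def size_b(self) -> int:
        return self.n_in_b + self.n_out_b

    @property
    def total(self) -> int:
        return self.size_a + self.size_b

    def transposed(self) -> "ContingencyTable2x2":
        """Swap the roles of the two sets (columns)."""
        return ContingencyTable2x2(self.n_in_b, self.n_in_a, self.n_out_b, self.n_out_a)


@dataclass(frozen=True)
class HypergeomQuery:
    """Parameters of one hypergeometric overlap question.

    Drawing ``draws`` items without replacement from a population of
    ``population`` items of which ``successes`` are marked, what is the
    chance of seeing at least ``observed`` marked items?
    """

    population: int
    successes: int
    draws: int
    observed: int

    def __post_init__(self) -> None:
        N, K, n, k = self.population, self.successes, self.draws, self.observed
        if not (0 <= K <= N):
            raise ValueError(f"successes must satisfy 0 <= K <= N, got K={K}, N={N}")
        if not (0 <= n <= N):
            raise ValueError(f"draws must satisfy 0 <= n <= N, got n={n}, N={N}")
        lo, hi = max(0, n + K - N), min(n, K)
        if not (lo <= k <= hi):
            raise ValueError(
                f"observed={k} outside the hypergeometric support [{lo}, {hi}]"
            )


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def _hypergeom_logpmf(N: int, K: int, n: int, k: np.ndarray) -> np.ndarray:
    return _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)


def fisher_exact_two_sided(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> PValue:
    """Fisher's exact test on a 2x2 table, two-sided by default.

    The two-sided p-value follows the minimum-likelihood convention:
    with the margins fixed, it sums the hypergeometric point
    probabilities of every table whose probability does not exceed that
    of the observed table (within a 1e-7 relative guard).  ``alternative``
    may be ``"greater"`` or ``"less"`` (enrichment / depletion of the
    category in set A) for one-sided sensitivity checks.

    A table with an empty row or column carries no information; p = 1 is
    returned with a warning.
    """
    a = table.n_in_a
    K = table.n_in_a + table.n_in_b  # category margin
    n = table.size_a  # set-A margin
    N = table.total
    if K == 0 or K == N or n == 0 or n == N:
        warnings.warn(
            "degenerate 2x2 table (empty row or column); p-value is 1",
            stacklevel=2,
        )
        return PValue.one()

    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    logpmf = _hypergeom_logpmf(N, K, n, support)
    log_obs = logpmf[a - lo]

    if alternative == "two-sided":
        mask = logpmf <= log_obs + math.log1p(_REL_ERR)
    elif alternative == "greater":
        mask = support >= a
    elif alternative == "less":
        mask = support <= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PValue(float(logsumexp(logpmf[mask])))


def hypergeom_sf(query: HypergeomQuery) -> PValue:
    """Upper-tail probability P(X >= observed) of the hypergeometric.

    Summed exactly in log space over the support from ``observed`` up;
    P(X >= lower support bound) is exactly 1.
    """
    N, K, n, k = query.population, query.successes, query.draws, query.observed
    hi = min(n, K)
    tail = np.arange(k, hi + 1)
    if tail.size == 0:  # unreachable given query validation, defensive
        return PValue(-math.inf)
    if k <= max(0, n + K - N):
        return PValue.one()
    return PValue(float(logsumexp(_hypergeom_logpmf(N, K, n, tail))))


def hypergeom_pmf(query: HypergeomQuery) -> PValue:
    """Point probability P(X = observed) of the hypergeometric."""
    N, K, n, k = query.population, query.successes, query.draws, query.observed
    return PValue(float(_hypergeom_logpmf(N, K, n, np.asarray([k]))[0]))


def benjamini_hochberg(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjustment.

    Returns adjusted p-values (q-values) in the input order: each raw p
    is multiplied by m/rank, the running minimum is enforced from the
    largest rank down, and results are clipped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out.tolist()


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of a two-sided Wilcoxon rank-sum (Mann-Whitney) test."""

    statistic: float  # Mann-Whitney U of the first sample
    p: float
    method: str  # "exact" or "asymptotic"


def rank_sum_test(sample_a, sample_b, exact_max_n: int = 10) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test between two samples.

    When both samples have at most ``exact_max_n`` observations the null
    distribution is enumerated exhaustively over all relabelings of the
    pooled values (midranks handle ties, so identical samples give
    p = 1 exactly).  Larger samples use the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")

    n_a, n_b = a.size, b.size
    if n_a <= exact_max_n and n_b <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        w_obs = ranks[:n_a].sum()
        mu = n_a * (n_a + n_b + 1) / 2.0
        dev_obs = abs(w_obs - mu)
        count = total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= dev_obs - 1e-9:
                count += 1
        u_obs = w_obs - n_a * (n_a + 1) / 2.0
        return RankSumResult(statistic=float(u_obs), p=count / total, method="exact")

    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(statistic=float(res.statistic), p=float(res.pvalue), method="asymptotic")
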