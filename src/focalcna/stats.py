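"""Shared statistical primitives.

Exact 2x2 tests are computed in integer arithmetic on the hypergeometric
support so that results are reproducible to machine precision and can be
checked against enumeration oracles without floating-point tie ambiguity.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_exact",
    "odds_ratio",
    "bh_qvalues",
    "rank_sum_test",
    "hypergeom_tail",
]


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int, alternative: str, method: str) -> float:
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    lo = max(0, k - r2)
    hi = min(k, r1)
    # integer numerators of the conditional hypergeometric pmf; the common
    # denominator C(n, k) cancels in all comparisons
    num = [math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)]
    total = sum(num)
    obs = num[a - lo]
    if alternative == "less":
        p = sum(num[: a - lo + 1])
    elif alternative == "greater":
        p = sum(num[a - lo:])
    elif alternative == "two-sided":
        if method == "minlike":
            # classical definition: all outcomes no more likely than observed
            p = sum(w for w in num if w <= obs)
        elif method == "central":
            lower = sum(num[: a - lo + 1])
            upper = sum(num[a - lo:])
            p = min(total, 2 * min(lower, upper))
        else:
            raise ValueError(f"unknown two-sided method: {method!r}")
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float(Fraction(p, total))


def fisher_exact(
    a: int, b: int, c: int, d: int,
    alternative: str = "two-sided",
    method: str = "minlike",
) -> float:
    """Exact Fisher p-value for the 2x2 table [[a, b], [c, d]].

    Parameters
    ----------
    alternative
        "two-sided", "less" or "greater" (on the first cell).
    method
        Two-sided convention. "minlike" (default) sums all tables whose
        conditional probability does not exceed the observed one — the
        definition used by R's ``fisher.test``. "central" doubles the
        smaller one-sided tail (capped at 1), the convention of central
        exact 2x2 tests and the power routines built on them.
    """
    return _fisher_cached(int(a), int(b), int(c), int(d), alternative, method)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c); infinite when b*c = 0 with a*d > 0."""
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q >= p elementwise).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    # p * m / rank >= p mathematically; clamp the 1-ulp float shortfall
    q_sorted = np.maximum(q_sorted, p[order])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null distribution when there are no ties and the combined sample
    size is at most 30; otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and pooled.size <= 30) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def hypergeom_tail(k: int, n_draws: int, n_success: int, n_pop: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(n_pop, n_success, n_draws)."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, n_pop, n_success, n_draws))
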