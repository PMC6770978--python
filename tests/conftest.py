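"""Shared fixtures and independent brute-force oracles.

The oracles here recompute p-values and scores from first principles
(exact rational arithmetic, explicit enumeration) and are deliberately
written without reference to the package's implementations.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from focalcna.genomics_io import CohortDesign
from focalcna.simulate import GeneratorConfig, generate_cohort, synthetic_signature_catalog


# ---------------------------------------------------------------------------
# Oracles

def fisher_oracle(a: int, b: int, c: int, d: int, method: str = "minlike") -> float:
    """Two-sided Fisher p by explicit enumeration in exact rationals."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    denom = math.comb(n, k)
    support = range(max(0, k - r2), min(k, r1) + 1)
    pmf = {x: Fraction(math.comb(r1, x) * math.comb(r2, k - x), denom) for x in support}
    obs = pmf[a]
    if method == "minlike":
        p = sum(v for v in pmf.values() if v <= obs)
    elif method == "central":
        lower = sum(pmf[x] for x in support if x <= a)
        upper = sum(pmf[x] for x in support if x >= a)
        p = min(Fraction(1), 2 * min(lower, upper))
    else:
        raise ValueError(method)
    return float(p)


def bh_oracle(pvalues) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up adjusted p-values."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = max(running, p[i])  # clamp the 1-ulp float shortfall of p*m/rank
    return np.array(q)


def hypergeom_tail_oracle(k: int, n_draws: int, n_success: int, n_pop: int) -> float:
    """P(overlap >= k) by exact rational enumeration."""
    denom = math.comb(n_pop, n_draws)
    total = Fraction(0)
    for x in range(k, min(n_draws, n_success) + 1):
        total += Fraction(math.comb(n_success, x)
                          * math.comb(n_pop - n_success, n_draws - x), denom)
    return float(min(total, Fraction(1)))


def es_oracle(ranked: pd.Series, members: set, weight: float = 1.0) -> float:
    """O(n) brute-force GSEA running sum, step by step."""
    order = ranked.sort_values(ascending=False, kind="mergesort")
    n = len(order)
    hits = [g in members for g in order.index]
    k = sum(hits)
    if k == n:
        return 0.0
    wsum = sum(abs(order.iloc[i]) ** weight for i in range(n) if hits[i])
    run, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            run += (abs(order.iloc[i]) ** weight / wsum) if wsum > 0 else 1.0 / k
        else:
            run -= 1.0 / (n - k)
        if abs(run) > abs(best):
            best = run
    return best


# ---------------------------------------------------------------------------
# Fixtures

@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort, shared across tests."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def catalog():
    return synthetic_signature_catalog()


@pytest.fixture()
def small_design():
    return CohortDesign({"r1": "R", "r2": "R", "s1": "fS", "s2": "fS"})
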