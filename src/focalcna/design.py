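"""Exact power and sample size for two-group binary-alteration screens.

For a gene altered with probability ``p1`` in one class and ``p2`` in the
other, the exact power of the two-sided Fisher test at a per-test level
``alpha`` is obtained by enumerating every pair of binomial outcomes:

    power = sum_{x=0..n1} sum_{y=0..n2}
            Bin(x; n1, p1) * Bin(y; n2, p2) * 1[p_Fisher(x, y) <= alpha]

When a screen of ``n_tests`` hypotheses is controlled at FDR level ``fdr``
and a single hypothesis is non-null, the Benjamini–Hochberg step-up reduces
to the per-test level ``fdr / n_tests``; that is the operational reading
used here.

The default two-sided convention is the *central* Fisher test (twice the
smaller one-sided tail, capped at 1), which is the convention of the exact
2x2 power/sample-size routines this module mirrors. The classical
minimum-likelihood convention used by the association modules is available
via ``method="minlike"``; at small, unbalanced sample sizes the two can
give noticeably different power (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import fisher_exact

__all__ = ["PowerSpec", "fisher_power", "required_sample_size"]

_MAX_N = 200  # exact enumeration regime


@dataclass(frozen=True)
class PowerSpec:
    """Specification of a two-group binary screen.

    p1, p2 : per-class alteration probabilities
    n1, n2 : group sizes
    n_tests: number of hypotheses in the screen
    fdr    : target FDR level; the derived per-test alpha is fdr / n_tests
    """
    p1: float
    p2: float
    n1: int
    n2: int
    n_tests: int = 1
    fdr: float = 0.05

    def __post_init__(self):
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("alteration probabilities must lie in [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if not 0.0 < self.fdr <= 1.0:
            raise ValueError("fdr must lie in (0, 1]")

    @property
    def per_test_alpha(self) -> float:
        return self.fdr / self.n_tests


def fisher_power(spec: PowerSpec, method: str = "central") -> float:
    """Exact power of the two-sided Fisher test under ``spec``.

    Fully deterministic; enumerates all (n1+1) x (n2+1) binomial outcome
    pairs. ``method`` selects the two-sided p-value convention
    ("central" or "minlike").
    """
    alpha = spec.per_test_alpha
    if alpha <= 0:
        raise ValueError("per-test alpha must be positive")
    if spec.n1 > _MAX_N or spec.n2 > _MAX_N:
        raise ValueError(f"exact enumeration supports group sizes up to {_MAX_N}")
    px = sps.binom.pmf(np.arange(spec.n1 + 1), spec.n1, spec.p1)
    py = sps.binom.pmf(np.arange(spec.n2 + 1), spec.n2, spec.p2)
    power = 0.0
    for x in range(spec.n1 + 1):
        for y in range(spec.n2 + 1):
            p = fisher_exact(x, spec.n1 - x, y, spec.n2 - y, method=method)
            if p <= alpha:
                power += px[x] * py[y]
    return float(power)


def required_sample_size(
    spec: PowerSpec,
    target_power: float = 0.80,
    method: str = "central",
    n_max: int = _MAX_N,
) -> int:
    """Smallest equal per-group n whose exact Fisher power reaches target.

    Searches n = 2, 3, ... upward with the per-test alpha derived from
    ``spec`` (group sizes in ``spec`` are ignored; the search is over
    equal groups).
    """
    if not 0.0 < target_power <= 1.0:
        raise ValueError("target_power must lie in (0, 1]")
    for n in range(2, n_max + 1):
        trial = PowerSpec(spec.p1, spec.p2, n, n, spec.n_tests, spec.fdr)
        if fisher_power(trial, method=method) >= target_power:
            return n
    raise ValueError(f"target power {target_power} not reached by n = {n_max}")
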