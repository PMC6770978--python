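"""RNA-seq count normalization, differential expression and enrichment.

Normalization is TMM (trimmed mean of M-values): per-sample scaling
factors from a doubly trimmed, inverse-variance-weighted mean of per-gene
log ratios against a reference sample, rescaled to geometric mean 1.

Differential expression is a moderated two-sample t on log-CPM: the
per-gene pooled variance is shrunk toward the cohort-mean variance with a
fixed weight. This deliberately replaces precision-weighted linear-model
pipelines: only the log fold-change and nominal p feed the downstream
copy-number/expression concordance filter, and the simpler statistic is
exactly checkable against a plain t-test in the zero-shrinkage limit (see
docs/methods.md for the substitution rationale).

Enrichment: pre-ranked GSEA (weighted Kolmogorov–Smirnov running sum,
weight exponent 1, gene-label permutation null) and hypergeometric
over-representation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .genomics_io import CohortDesign
from .stats import bh_qvalues, hypergeom_tail

__all__ = [
    "tmm_norm_factors", "cpm", "log_cpm", "filter_low_expressed",
    "differential_expression", "enrichment_score", "preranked_gsea",
    "over_representation",
]


# ---------------------------------------------------------------------------
# TMM

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """log2 scaling factor of one sample against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        po, pr = obs / lib_obs, ref / lib_ref
        m = np.log2(po / pr)
        a = 0.5 * (np.log2(po) + np.log2(pr))
    # genes with zero counts in either sample are excluded
    fin = np.isfinite(m) & np.isfinite(a)
    m, a = m[fin], a[fin]
    obs_f, ref_f = obs[fin], ref[fin]
    n = m.size
    if n == 0:
        return 0.0
    # asymptotic binomial variance of M
    v = (lib_obs - obs_f) / (lib_obs * obs_f) + (lib_ref - ref_f) / (lib_ref * ref_f)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_norm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                     trim_a: float = 0.05) -> pd.Series:
    """TMM normalization factors, geometric mean 1.

    The reference sample is the one whose upper quartile of CPM-scaled
    counts is closest to the mean upper quartile. M-values (log ratios)
    are trimmed by ``trim_m`` on each side and A-values (log abundances)
    by ``trim_a``; the surviving M-values are averaged with weights equal
    to inverse asymptotic binomial variances.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = [counts.columns[i] for i in np.where(lib <= 0)[0]]
        raise ValueError(f"sample(s) with zero total count: {bad}")
    uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.array([
        _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(x.shape[1])
    ])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _effective_lib(counts: pd.DataFrame, norm_factors: pd.Series | None) -> pd.Series:
    lib = counts.sum(axis=0)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(lib.index)
    return lib


def cpm(counts: pd.DataFrame, norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over (TMM-effective) library sizes."""
    lib = _effective_lib(counts, norm_factors)
    return counts.div(lib, axis=1) * 1e6


def log_cpm(counts: pd.DataFrame, norm_factors: pd.Series | None = None,
            prior: float = 0.5) -> pd.DataFrame:
    """log2 CPM with a prior count: log2(1e6 * (count + prior) / (lib + 2*prior))."""
    lib = _effective_lib(counts, norm_factors)
    return np.log2((counts + prior).div(lib + 2 * prior, axis=1) * 1e6)


def filter_low_expressed(counts: pd.DataFrame, cpm_min: float = 1.0,
                         frac_min: float = 0.05,
                         norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Keep genes with CPM >= cpm_min in at least ceil(frac_min * n) samples."""
    need = math.ceil(frac_min * counts.shape[1])
    ok = (cpm(counts, norm_factors) >= cpm_min).sum(axis=1) >= need
    return counts.loc[ok]


# ---------------------------------------------------------------------------
# Differential expression

def differential_expression(
    counts: pd.DataFrame,
    design: CohortDesign,
    norm_factors: pd.Series | None = None,
    shrink: float = 0.1,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Moderated two-sample t per gene on log-CPM, R vs fS.

    logFC = mean log2-CPM(R) - mean log2-CPM(fS). The pooled per-gene
    variance is shrunk toward the cohort-mean variance:
    s2_used = (1 - shrink) * s2_gene + shrink * mean(s2_gene); with
    shrink = 0 the statistic is the ordinary equal-variance t. p-values
    use the t distribution with n1 + n2 - 2 degrees of freedom; BH q
    across genes.
    """
    if not 0.0 <= shrink < 1.0:
        raise ValueError("shrink must lie in [0, 1)")
    r = [s for s in counts.columns if design[s] == "R"]
    fs = [s for s in counts.columns if design[s] == "fS"]
    n1, n2 = len(r), len(fs)
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least two samples with counts")
    lc = log_cpm(counts, norm_factors, prior)
    xr, xf = lc[r].to_numpy(), lc[fs].to_numpy()
    logfc = xr.mean(axis=1) - xf.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (xr.var(axis=1, ddof=1) * (n1 - 1) + xf.var(axis=1, ddof=1) * (n2 - 1)) / df
    s2_used = (1.0 - shrink) * s2 + shrink * s2.mean()
    se = np.sqrt(s2_used * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    out = pd.DataFrame({"log2fc": logfc, "t": t, "p": p, "q": bh_qvalues(p)},
                       index=counts.index)
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# Pre-ranked GSEA

def enrichment_score(ranked: pd.Series, members: set[str], weight: float = 1.0) -> float:
    """Weighted KS enrichment score of a gene set on a ranked statistic.

    ``ranked`` maps gene -> statistic and is sorted internally in
    decreasing order. Hits advance the running sum by |stat|^weight
    (normalized), misses retreat by 1/(n - k); the ES is the extreme
    deviation from zero. A set covering every ranked gene has no miss
    steps and its ES is defined as 0.
    """
    order = ranked.sort_values(ascending=False, kind="mergesort")
    n = order.size
    hit = order.index.isin(members)
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set has no member among the ranked genes")
    if k == n:
        return 0.0
    pos = np.flatnonzero(hit)                      # 0-based positions of hits
    w = np.abs(order.to_numpy()[pos]) ** weight
    wsum = w.sum()
    cum_hit = np.cumsum(w) / wsum if wsum > 0 else np.arange(1, k + 1) / k
    miss_step = 1.0 / (n - k)
    idx = np.arange(1, k + 1)
    dev_after = cum_hit - (pos + 1 - idx) * miss_step        # just after each hit
    dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - (idx - 1)) * miss_step
    hi, lo = dev_after.max(), dev_before.min()
    return float(hi if hi >= -lo else lo)


def preranked_gsea(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int | None = None,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Pre-ranked gene-set enrichment with a gene-label permutation null.

    The null redraws each set's positions uniformly among the ranked genes
    (equivalently, permutes gene labels). The p-value is one-sided among
    null scores of the same sign as the observed ES; NES divides the ES by
    the mean |null ES| of that sign. BH q across sets.
    """
    order = ranked.sort_values(ascending=False, kind="mergesort")
    stats_arr = order.to_numpy()
    n = order.size
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        mem = set(members)
        es = enrichment_score(order, mem, weight)
        k = int(order.index.isin(mem).sum())
        null = np.empty(n_perm)
        proxy = pd.Series(stats_arr, index=pd.RangeIndex(n))
        for b in range(n_perm):
            pos = rng.choice(n, size=k, replace=False)
            null[b] = enrichment_score(proxy, set(pos), weight)
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        p = (1.0 + np.sum(np.abs(null[same]) >= abs(es))) / (1.0 + n_same)
        denom = np.abs(null[same]).mean() if n_same else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        rows.append({"gene_set": name, "size": k, "es": es, "nes": nes, "p": p,
                     "direction": "up" if es >= 0 else "down"})
    out = pd.DataFrame(rows).set_index("gene_set")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Over-representation

def over_representation(
    selected: list[str] | set[str],
    gene_sets: dict[str, list[str]],
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    All sets are intersected with the universe first; p = P(overlap >= k)
    under sampling len(selected & universe) genes without replacement.
    """
    uni = set(universe)
    sel = set(selected) & uni
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        k = len(sel & in_uni)
        p = hypergeom_tail(k, len(sel), len(in_uni), len(uni))
        rows.append({"gene_set": name, "set_size": len(in_uni), "overlap": k, "p": p})
    out = pd.DataFrame(rows).set_index("gene_set")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out
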