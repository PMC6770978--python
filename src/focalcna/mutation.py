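"""Somatic mutation analysis.

Impact filtering, tumor mutational load, recurrently mutated genes,
pathway-level mutation aggregation, per-gene class enrichment, 96-context
mutational spectra and signature deconvolution (forward selection with
non-negative weights), and signature-based hierarchical clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls

from .cna import class_association
from .genomics_io import CohortDesign, MutationRecord
from .stats import fisher_exact, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_IMPACT_MAP", "SPECTRUM_CONTEXTS", "SignatureExposure",
    "impact_of", "filter_by_impact", "mutational_load", "top_mutated_genes",
    "mutation_matrix", "pathway_mutation_status", "gene_class_enrichment",
    "fold_snv", "spectrum_from_records", "fit_signatures", "fit_signatures_cohort",
    "signature_class_comparison", "cluster_by_signatures",
]

#: Variant class -> impact. High/moderate classes disrupt the protein
#: (truncation, loss of function, NMD, amino-acid change); unknown classes
#: map to "unknown" and are excluded by the disruptive filter.
DEFAULT_IMPACT_MAP: dict[str, str] = {
    "Nonsense_Mutation": "high",
    "Nonstop_Mutation": "high",
    "Frame_Shift_Del": "high",
    "Frame_Shift_Ins": "high",
    "Splice_Site": "high",
    "Translation_Start_Site": "high",
    "Missense_Mutation": "moderate",
    "In_Frame_Del": "moderate",
    "In_Frame_Ins": "moderate",
    "Silent": "low",
    "5'UTR": "modifier",
    "3'UTR": "modifier",
    "5'Flank": "modifier",
    "3'Flank": "modifier",
    "Intron": "modifier",
    "IGR": "modifier",
    "RNA": "modifier",
    "Targeted_Region": "modifier",
}


def impact_of(variant_class: str, mapping: dict[str, str] | None = None) -> str:
    return (mapping or DEFAULT_IMPACT_MAP).get(variant_class, "unknown")


def filter_by_impact(
    records: list[MutationRecord],
    keep: frozenset[str] | set[str] = frozenset({"high", "moderate"}),
    mapping: dict[str, str] | None = None,
) -> list[MutationRecord]:
    """Keep records whose mapped impact is in ``keep`` (default: disruptive)."""
    return [r for r in records if impact_of(r.variant_class, mapping) in keep]


def mutational_load(
    records: list[MutationRecord],
    design: CohortDesign,
    mode: str = "all",
    mapping: dict[str, str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-sample mutation counts and the Wilcoxon class comparison.

    mode "all" counts every record; "disruptive" counts only high/moderate
    impact. Samples in the design with no records count 0.
    Returns (counts indexed by sample, two-sided rank-sum p-value R vs fS).
    """
    if mode == "disruptive":
        records = filter_by_impact(records, mapping=mapping)
    elif mode != "all":
        raise ValueError(f"mode must be 'all' or 'disruptive', got {mode!r}")
    counts = pd.Series(0, index=pd.Index(design.samples(), name="sample_id"), dtype=int)
    for r in records:
        if r.sample_id in counts.index:
            counts[r.sample_id] += 1
    p = rank_sum_test(counts[design.samples("R")], counts[design.samples("fS")])
    return counts, p


def top_mutated_genes(records: list[MutationRecord], min_patients: int = 3) -> pd.DataFrame:
    """Genes mutated in at least ``min_patients`` distinct samples.

    ``n_samples`` counts distinct mutated samples (a sample with several
    hits in the gene counts once); ``multi_hit`` flags genes with more
    than one mutation in the same sample.
    """
    per_gene: dict[str, dict[str, int]] = {}
    for r in records:
        per_gene.setdefault(r.gene_id, {}).setdefault(r.sample_id, 0)
        per_gene[r.gene_id][r.sample_id] += 1
    rows = [
        {"gene_id": g, "n_samples": len(hits), "n_records": sum(hits.values()),
         "multi_hit": any(v > 1 for v in hits.values())}
        for g, hits in per_gene.items() if len(hits) >= min_patients
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "n_samples", "n_records", "multi_hit"])
    return df.sort_values(["n_samples", "gene_id"], ascending=[False, True]).set_index("gene_id")


def mutation_matrix(records: list[MutationRecord], samples: list[str]) -> pd.DataFrame:
    """Binary gene x sample mutated/not matrix over the given samples."""
    genes = sorted({r.gene_id for r in records})
    m = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=samples)
    for r in records:
        if r.sample_id in m.columns and r.gene_id in m.index:
            m.loc[r.gene_id, r.sample_id] = 1
    return m


def pathway_mutation_status(
    records: list[MutationRecord],
    gene_sets: dict[str, list[str]],
    samples: list[str],
) -> pd.DataFrame:
    """Pathway x sample binary matrix: 1 iff >= 1 member gene is mutated."""
    gm = mutation_matrix(records, samples)
    rows = {}
    for name, members in gene_sets.items():
        present = [g for g in members if g in gm.index]
        rows[name] = (gm.loc[present].sum(axis=0) > 0).astype(int) if present \
            else pd.Series(0, index=gm.columns)
    out = pd.DataFrame(rows).T
    out.index.name = "pathway"
    return out


def gene_class_enrichment(records: list[MutationRecord], design: CohortDesign) -> pd.DataFrame:
    """Per-gene Fisher association of mutated/not with the class (BH across genes)."""
    return class_association(mutation_matrix(records, design.samples()), design,
                             direction="mutation")


# ---------------------------------------------------------------------------
# 96-context spectra

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: Fixed 96-bin ordering: substitution-major (C>A, C>G, C>T, T>A, T>C, T>G),
#: then 5' flank and 3' flank each in A, C, G, T order.
SPECTRUM_CONTEXTS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS for five in _BASES for three in _BASES
]
_CONTEXT_INDEX = {c: i for i, c in enumerate(SPECTRUM_CONTEXTS)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fold_snv(ref: str, alt: str, context: str) -> str:
    """Fold an SNV onto the pyrimidine strand and return its 96-bin label.

    Substitutions are expressed with a C or T reference; purine-reference
    events are reverse-complemented (alleles and flanking context alike),
    so every SNV maps to exactly one of the 96 bins.
    """
    if context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref in "AG":
        ref, alt, context = _revcomp(ref), _revcomp(alt), _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def spectrum_from_records(
    records: list[MutationRecord],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample 96-context counts (rows: contexts in the fixed order).

    Non-SNV records and SNVs lacking a trinucleotide context are skipped;
    the number skipped is logged.
    """
    if samples is None:
        samples = sorted({r.sample_id for r in records})
    counts = pd.DataFrame(0, index=pd.Index(SPECTRUM_CONTEXTS, name="context"),
                          columns=samples, dtype=int)
    skipped = 0
    for r in records:
        if r.sample_id not in counts.columns:
            continue
        if not r.is_snv or r.trinucleotide_context is None:
            skipped += 1
            continue
        label = fold_snv(r.ref_allele, r.alt_allele, r.trinucleotide_context)
        counts.loc[label, r.sample_id] += 1
    if skipped:
        logger.info("spectrum_from_records: skipped %d non-SNV/contextless records", skipped)
    return counts


# ---------------------------------------------------------------------------
# Signature deconvolution

@dataclass
class SignatureExposure:
    """Fitted signature weights for one sample's spectrum."""
    sample_id: str
    weights: pd.Series          # indexed by signature name, in [0, 1], sum <= 1
    unexplained: float          # 1 - sum(weights)
    reconstruction_error: float  # L2 norm of the residual on proportions


def _check_catalog(catalog: pd.DataFrame) -> None:
    if catalog.shape[1] == 0:
        raise ValueError("signature catalog is empty")
    if catalog.shape[0] != 96:
        raise ValueError("signature catalog must have 96 context rows")
    if (catalog.to_numpy() < 0).any():
        raise ValueError("signature catalog entries must be non-negative")
    colsums = catalog.sum(axis=0).to_numpy()
    if np.any(np.abs(colsums - 1.0) > 1e-6):
        raise ValueError("signature catalog columns must sum to 1 (within 1e-6)")


def _fit_support(s: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares weights >= 0 with sum <= 1 for p ~ s @ w; returns (w, sse).

    The unconstrained NNLS solution usually already satisfies sum <= 1
    because both the spectrum and the catalog columns are probability
    vectors; when it does not, the sum constraint is activated via a
    heavily weighted penalty row (an NNLS re-solve), with a final
    renormalization guaranteeing the bound exactly.
    """
    w, _ = nnls(s, p)
    if w.sum() > 1.0:
        lam = 1e4
        s_aug = np.vstack([s, lam * np.ones((1, s.shape[1]))])
        p_aug = np.concatenate([p, [lam]])
        w, _ = nnls(s_aug, p_aug)
        if w.sum() > 1.0:
            w = w / w.sum()
    return w, float(np.sum((s @ w - p) ** 2))


def fit_signatures(
    spectrum: pd.Series | np.ndarray,
    catalog: pd.DataFrame,
    retention_cutoff: float = 0.06,
    improvement_tol: float = 1e-3,
    sample_id: str = "",
) -> SignatureExposure:
    """Deconvolve one spectrum into catalog signature exposures.

    The spectrum is normalized to proportions, then signatures are added
    by forward selection: at each step the candidate whose inclusion most
    reduces the squared reconstruction error (under non-negative weights
    summing to at most 1) joins the support; selection stops when the
    relative error improvement falls below ``improvement_tol``. Weights
    below ``retention_cutoff`` are zeroed and the model is re-fit on the
    retained support (repeated until stable), so reported weights are
    either 0 or at least the cutoff.
    """
    _check_catalog(catalog)
    x = np.asarray(spectrum, dtype=float).ravel()
    if x.shape[0] != 96:
        raise ValueError("spectrum must have 96 context counts")
    total = x.sum()
    if total < 1:
        raise ValueError("spectrum must contain at least one mutation")
    p = x / total
    s_all = catalog.to_numpy(dtype=float)
    names = list(catalog.columns)

    support: list[int] = []
    sse = float(np.sum(p ** 2))  # empty-model error
    while len(support) < len(names):
        best_j, best_w, best_sse = -1, None, sse
        for j in range(len(names)):
            if j in support:
                continue
            w, err = _fit_support(s_all[:, support + [j]], p)
            if err < best_sse - 1e-15:
                best_j, best_w, best_sse = j, w, err
        if best_j < 0 or sse <= 0:
            break
        if (sse - best_sse) / sse < improvement_tol:
            break
        support.append(best_j)
        sse = best_sse
        w_full = best_w

    weights = np.zeros(len(names))
    if support:
        weights[support] = w_full
        # enforce the retention cutoff, re-fitting until stable
        while True:
            keep = [j for j in support if weights[j] >= retention_cutoff]
            if len(keep) == len(support):
                break
            weights[:] = 0.0
            support = keep
            if not support:
                sse = float(np.sum(p ** 2))
                break
            w, sse = _fit_support(s_all[:, support], p)
            weights[support] = w
    recon_err = float(np.sqrt(sse))
    return SignatureExposure(
        sample_id=sample_id,
        weights=pd.Series(weights, index=names),
        unexplained=float(1.0 - weights.sum()),
        reconstruction_error=recon_err,
    )


def fit_signatures_cohort(
    spectra: pd.DataFrame,
    catalog: pd.DataFrame,
    retention_cutoff: float = 0.06,
    improvement_tol: float = 1e-3,
) -> pd.DataFrame:
    """Exposure matrix (samples x signatures) for a cohort of spectra."""
    rows = {}
    for sample in spectra.columns:
        exp = fit_signatures(spectra[sample], catalog, retention_cutoff,
                             improvement_tol, sample_id=sample)
        rows[sample] = exp.weights
    out = pd.DataFrame(rows).T.reindex(columns=catalog.columns)
    out.index.name = "sample_id"
    return out


def signature_class_comparison(exposures: pd.DataFrame, design: CohortDesign) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p per signature score, R vs fS."""
    r = [s for s in exposures.index if design[s] == "R"]
    fs = [s for s in exposures.index if design[s] == "fS"]
    return pd.Series({sig: rank_sum_test(exposures.loc[r, sig], exposures.loc[fs, sig])
                      for sig in exposures.columns}, name="wilcoxon_p")


def cluster_by_signatures(
    exposures: pd.DataFrame,
    design: CohortDesign | None = None,
    top_k: int = 5,
    n_clusters: int = 2,
):
    """Hierarchical clustering of samples on their top-k signature scores.

    The top-k signatures are chosen by mean weight across samples;
    clustering is agglomerative with Euclidean distance and Ward linkage.
    Returns (linkage matrix, flat cluster labels as a Series, Fisher p for
    the cluster/class 2x2 association, or None without a design).
    """
    top = exposures.mean(axis=0).sort_values(ascending=False).index[:top_k]
    x = exposures[top].to_numpy()
    z = linkage(x, method="ward", metric="euclidean")
    labels = pd.Series(fcluster(z, t=n_clusters, criterion="maxclust"),
                       index=exposures.index, name="cluster")
    p = None
    if design is not None:
        a = sum(1 for s in exposures.index if labels[s] == 1 and design[s] == "R")
        b = sum(1 for s in exposures.index if labels[s] == 1 and design[s] == "fS")
        c = sum(1 for s in exposures.index if labels[s] != 1 and design[s] == "R")
        d = sum(1 for s in exposures.index if labels[s] != 1 and design[s] == "fS")
        p = fisher_exact(a, b, c, d)
    return z, labels, p
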