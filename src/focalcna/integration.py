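"""Copy-number / expression concordance and end-to-end orchestration.

The gene-selection decision tree joins the gene-level amp/del class
association with differential expression in four ordered, monotone steps:

1. keep genes with nominal Fisher p < p_cut in the amp or del analysis;
2. drop genes not assessed by RNA-seq (absent from the DE table);
3. assign each gene the direction of the class with the strictly higher
   alteration frequency (amp_in_R, amp_in_fS, del_in_R or del_in_fS);
   genes with equal frequencies are dropped and logged;
4. keep genes whose expression change is concordant with the copy-number
   direction (amplified-in-X => higher expression in X; deleted-in-X =>
   lower in X) and whose |log2FC| meets the fold-change cut.

A gene qualifying in both the amp and del analyses resolves to the
direction with the smaller Fisher p; ties are dropped and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cna, expression, genomics_io as gio, mutation
from .genomics_io import CohortDesign, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "concordance_filter", "summarize_cytobands",
    "PipelineConfig", "run_pipeline",
]

_DIRECTIONS = ("amp_in_R", "amp_in_fS", "del_in_R", "del_in_fS")


def _favored(row, min_freq_diff: float) -> str | None:
    if row["freq_R"] > row["freq_fS"] + min_freq_diff:
        return "R"
    if row["freq_fS"] > row["freq_R"] + min_freq_diff:
        return "fS"
    return None


def concordance_filter(
    amp_assoc: pd.DataFrame,
    del_assoc: pd.DataFrame,
    de_result: pd.DataFrame,
    gene_models: list[GeneModel],
    p_cut: float = 0.05,
    fc_cut: float = 0.5,
    min_freq_diff: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four-step concordance decision tree.

    ``amp_assoc``/``del_assoc`` are per-gene class-association tables (as
    from :func:`focalcna.cna.class_association`) carrying ``p``, ``q``,
    ``freq_R`` and ``freq_fS``; ``de_result`` carries ``log2fc`` (R vs fS).
    Returns the selected-gene table sorted by (p, -|log2FC|) and the gene
    count surviving each step.
    """
    cytoband = {g.gene_id: g.cytoband for g in gene_models}

    # step 1: nominal Fisher significance in either direction
    candidates: dict[str, tuple[str, pd.Series]] = {}
    dropped_ties = []
    for gene in set(amp_assoc.index[amp_assoc["p"] < p_cut]) | \
            set(del_assoc.index[del_assoc["p"] < p_cut]):
        pa = amp_assoc.loc[gene, "p"] if gene in amp_assoc.index else np.inf
        pd_ = del_assoc.loc[gene, "p"] if gene in del_assoc.index else np.inf
        hit_a, hit_d = pa < p_cut, pd_ < p_cut
        if hit_a and hit_d:
            if pa == pd_:
                dropped_ties.append(gene)
                logger.info("gene %s significant in both directions with tied p; dropped", gene)
                continue
            kind = "amp" if pa < pd_ else "del"
        else:
            kind = "amp" if hit_a else "del"
        candidates[gene] = (kind, (amp_assoc if kind == "amp" else del_assoc).loc[gene])
    n_step1 = len(candidates) + len(dropped_ties)

    # step 2: assessed by RNA-seq
    candidates = {g: v for g, v in candidates.items() if g in de_result.index}
    n_step2 = len(candidates)

    # step 3: strictly favored class
    directed: dict[str, tuple[str, pd.Series]] = {}
    for gene, (kind, row) in candidates.items():
        cls = _favored(row, min_freq_diff)
        if cls is None:
            logger.info("gene %s has no favored class (equal frequencies); dropped", gene)
            continue
        directed[gene] = (f"{kind}_in_{cls}", row)
    n_step3 = len(directed)

    # step 4: concordant expression at the fold-change cut
    rows = []
    for gene, (direction, row) in directed.items():
        lfc = float(de_result.loc[gene, "log2fc"])
        expected_sign = {"amp_in_R": 1, "del_in_R": -1,
                         "amp_in_fS": -1, "del_in_fS": 1}[direction]
        if np.sign(lfc) == expected_sign and abs(lfc) >= fc_cut:
            rows.append({
                "gene_id": gene, "direction": direction,
                "freq_R": row["freq_R"], "freq_fS": row["freq_fS"],
                "fisher_p": row["p"], "fisher_q": row["q"],
                "log2fc": lfc, "cytoband": cytoband.get(gene, ""),
            })
    cols = ["gene_id", "direction", "freq_R", "freq_fS", "fisher_p",
            "fisher_q", "log2fc", "cytoband"]
    out = pd.DataFrame(rows, columns=cols)
    out["abs_lfc"] = out["log2fc"].abs()
    out = (out.sort_values(["fisher_p", "abs_lfc", "gene_id"],
                           ascending=[True, False, True])
           .drop(columns="abs_lfc").set_index("gene_id"))
    steps = {"fisher_significant": n_step1, "assessed_by_rnaseq": n_step2,
             "favored_class": n_step3, "concordant": len(out)}
    return out, steps


def summarize_cytobands(selected: pd.DataFrame) -> dict[str, pd.Series]:
    """Relative cytoband frequencies among selected genes, per alteration type.

    Returns {"amp": Series, "del": Series}; each series sums to 1 (empty
    selections yield empty series, never a division by zero).
    """
    out: dict[str, pd.Series] = {}
    for kind in ("amp", "del"):
        sub = selected[selected["direction"].str.startswith(kind)] if len(selected) else selected
        if len(sub) == 0:
            out[kind] = pd.Series(dtype=float)
            continue
        freq = sub["cytoband"].value_counts(sort=True) / len(sub)
        freq.index.name = "cytoband"
        out[kind] = freq
    return out


# ---------------------------------------------------------------------------
# Orchestration

@dataclass
class PipelineConfig:
    """Input paths and parameters of a full run; loadable from YAML."""
    seg: str
    maf: str
    counts: str
    design: str
    gene_models: str
    signature_catalog: str | None = None
    gene_sets: str | None = None          # GMT for GSEA / ORA / pathway status
    low_thr: float = cna.DEFAULT_LOW_THR
    high_thr: float = cna.DEFAULT_HIGH_THR
    fdr_cut: float = 0.1
    p_cut: float = 0.05
    fc_cut: float = 0.5
    min_freq_diff: float = 0.0
    cpm_min: float = 1.0
    frac_min: float = 0.05
    n_perm_gscore: int = 1000
    n_perm_gsea: int = 500
    retention_cutoff: float = 0.06
    improvement_tol: float = 1e-3
    top_k_signatures: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run cna -> mutation -> expression -> integration on configured inputs.

    Writes every stage table as TSV plus ``summary.json`` (gene counts
    surviving each decision-tree step, seeds and parameters) and a run
    manifest. Deterministic given the configured seed. Returns the summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    segments = gio.read_seg(config.seg)
    records = gio.read_maf(config.maf)
    counts = gio.read_matrix(config.counts)
    design = gio.read_design(config.design)
    genes = gio.read_gene_models(config.gene_models)
    gene_sets = gio.read_gmt(config.gene_sets) if config.gene_sets else None
    catalog = gio.read_matrix(config.signature_catalog) if config.signature_catalog else None

    written: list[str] = []

    def emit(df: pd.DataFrame, name: str):
        _write_tsv(df, out / name)
        written.append(name)

    # --- copy number
    matrix = cna.calls_from_segments(segments, genes, config.low_thr,
                                     config.high_thr, samples=design.samples())
    emit(matrix.call_frame(), "gene_calls.tsv")
    emit(matrix.log2_frame(), "gene_log2.tsv")
    inst = cna.instability(segments, matrix)
    inst_p = cna.compare_instability(inst, design)
    emit(inst.assign(cls=[design[s] for s in inst.index]), "instability.tsv")
    emit(inst_p.to_frame(), "instability_tests.tsv")

    assoc = {}
    regions_rows = []
    for direction in ("amp", "del"):
        track = cna.g_scores(matrix, direction, config.low_thr,
                             n_perm=config.n_perm_gscore, seed=config.seed)
        emit(track.frame(), f"gscore_{direction}.tsv")
        for reg in cna.recurrent_regions(track, matrix.genes, config.fdr_cut):
            regions_rows.append({
                "direction": reg.direction, "chrom": reg.chrom,
                "n_genes": len(reg.gene_ids),
                "cytobands": ",".join(reg.cytobands),
                "genes": ",".join(reg.gene_ids), "peak_q": reg.peak_q,
            })
        binary = cna.binarize(matrix.call_frame(), direction)
        assoc[direction] = cna.class_association(binary, design, direction=direction)
        emit(assoc[direction], f"association_{direction}.tsv")
    emit(pd.DataFrame(regions_rows,
                      columns=["direction", "chrom", "n_genes", "cytobands",
                               "genes", "peak_q"]).set_index("direction"),
         "recurrent_regions.tsv")

    # --- mutations
    load_rows = {}
    for mode in ("all", "disruptive"):
        counts_m, p = mutation.mutational_load(records, design, mode=mode)
        load_rows[f"n_{mode}"] = counts_m
        load_rows.setdefault("wilcoxon_p", {})[mode] = p
    load_p = load_rows.pop("wilcoxon_p")
    emit(pd.DataFrame(load_rows), "mutational_load.tsv")
    emit(mutation.top_mutated_genes(records), "top_mutated_genes.tsv")
    emit(mutation.gene_class_enrichment(records, design), "mutation_enrichment.tsv")
    if gene_sets:
        pstat = mutation.pathway_mutation_status(records, gene_sets, design.samples())
        emit(cna.class_association(pstat, design, direction="pathway"),
             "pathway_association.tsv")

    cluster_p = None
    signature_tests = None
    if catalog is not None:
        spectra = mutation.spectrum_from_records(records, design.samples())
        emit(spectra, "spectra96.tsv")
        exposures = mutation.fit_signatures_cohort(
            spectra.loc[:, spectra.sum(axis=0) > 0], catalog,
            config.retention_cutoff, config.improvement_tol)
        emit(exposures, "signature_exposures.tsv")
        signature_tests = mutation.signature_class_comparison(
            exposures, design)
        emit(signature_tests.to_frame(), "signature_tests.tsv")
        _, labels, cluster_p = mutation.cluster_by_signatures(
            exposures, design, top_k=config.top_k_signatures)
        emit(labels.to_frame(), "signature_clusters.tsv")

    # --- expression
    factors = expression.tmm_norm_factors(counts)
    kept = expression.filter_low_expressed(counts, config.cpm_min,
                                           config.frac_min, factors)
    de = expression.differential_expression(kept, design, factors)
    emit(factors.to_frame(), "tmm_factors.tsv")
    emit(de, "differential_expression.tsv")
    if gene_sets:
        gsea = expression.preranked_gsea(de["t"], gene_sets,
                                         n_perm=config.n_perm_gsea,
                                         seed=config.seed)
        emit(gsea, "gsea.tsv")

    # --- integration
    selected, steps = concordance_filter(
        assoc["amp"], assoc["del"], de, genes,
        p_cut=config.p_cut, fc_cut=config.fc_cut,
        min_freq_diff=config.min_freq_diff)
    emit(selected, "concordant_genes.tsv")
    bands = summarize_cytobands(selected)
    band_df = pd.concat(
        {k: v for k, v in bands.items()}, names=["type", "cytoband"]
    ).rename("rel_freq").to_frame() if any(len(v) for v in bands.values()) \
        else pd.DataFrame(columns=["rel_freq"])
    emit(band_df, "cytoband_summary.tsv")
    if gene_sets and len(selected):
        ora = expression.over_representation(list(selected.index), gene_sets,
                                             list(de.index))
        emit(ora, "concordant_ora.tsv")

    summary = {
        "parameters": {
            k: getattr(config, k) for k in (
                "low_thr", "high_thr", "fdr_cut", "p_cut", "fc_cut",
                "min_freq_diff", "cpm_min", "frac_min", "n_perm_gscore",
                "n_perm_gsea", "retention_cutoff", "improvement_tol",
                "top_k_signatures", "seed")
        },
        "n_samples": {"R": design.n_R, "fS": design.n_fS},
        "decision_tree": steps,
        "n_selected": {
            "amp": int(selected["direction"].str.startswith("amp").sum()) if len(selected) else 0,
            "del": int(selected["direction"].str.startswith("del").sum()) if len(selected) else 0,
        },
        "n_recurrent_regions": {
            "amp": sum(1 for r in regions_rows if r["direction"] == "amp"),
            "del": sum(1 for r in regions_rows if r["direction"] == "del"),
        },
        "instability_wilcoxon_p": {k: float(v) for k, v in inst_p.items()},
        "mutational_load_wilcoxon_p": {k: float(v) for k, v in load_p.items()},
        "signature_cluster_fisher_p": cluster_p,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    (out / "manifest.json").write_text(
        json.dumps({"outputs": sorted(written) + ["summary.json"]},
                   indent=1, sort_keys=True) + "\n")
    return summary
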