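"""Seeded synthetic two-class tumor cohort generator.

Emits the full input bundle every analysis stage consumes — segmented
copy-number profiles, a somatic-mutation table with trinucleotide
contexts, an RNA-seq count matrix, the sample design, and a gene model
with cytobands — together with the planted ground truth, so recovery and
calibration suites can score the pipeline against known answers.

The default configuration mirrors a small platinum-resistance cohort:
11 resistant (R) vs 16 frankly sensitive (fS) samples; planted amplified
genes altered in 57% of R vs 12% of fS samples and planted deleted genes
in 15% of R vs 62% of fS; a dominant TP53-like gene mutated in 89% of
samples; and class-specific mutational-signature mixtures shifted by 0.3
between a clock-like and an HRD-like synthetic signature. Expression is
negative-binomial with a dosage term: mean scaled by 2^(slope * call).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics_io import (
    CohortDesign, GeneModel, MutationRecord, Segment,
    write_design, write_gene_models, write_maf, write_matrix, write_seg,
)
from .mutation import SPECTRUM_CONTEXTS

__all__ = [
    "GeneratorConfig", "GroundTruth", "SyntheticCohort",
    "synthetic_signature_catalog", "generate_cohort", "generate_null_cohort",
    "recovery_config",
]

_CATALOG_SEED = 96301  # fixed so signature identities are stable across runs


def synthetic_signature_catalog(n_signatures: int = 30,
                                seed: int = _CATALOG_SEED) -> pd.DataFrame:
    """Synthetic stand-in for a 30-signature trinucleotide catalog.

    Columns are sparse Dirichlet draws over the 96 contexts, hence
    column-stochastic and mutually well separated; this is a synthetic
    test catalog, not the COSMIC matrix (which users supply as a TSV).
    """
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(96, 0.08), size=n_signatures).T
    names = [f"Signature_{i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(cols, index=pd.Index(SPECTRUM_CONTEXTS, name="context"),
                        columns=names)


def _default_mix_R() -> dict[str, float]:
    return {"Signature_1": 0.55, "Signature_3": 0.15, "Signature_5": 0.30}


def _default_mix_fS() -> dict[str, float]:
    return {"Signature_1": 0.25, "Signature_3": 0.45, "Signature_5": 0.30}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort, with cohort-scale defaults.

    Alteration frequencies are per planted gene, per sample, conditional
    on class. ``dosage_slope`` is the log2-expression shift per call unit;
    ``dispersion`` the negative-binomial overdispersion (var = m + d*m^2).
    """
    seed: int
    n_R: int = 11
    n_fS: int = 16
    n_chrom: int = 2
    genes_per_chrom: int = 500
    genes_per_cytoband: int = 25
    n_planted_amp: int = 50
    n_planted_del: int = 50
    amp_freq_R: float = 0.57
    amp_freq_fS: float = 0.12
    del_freq_R: float = 0.15
    del_freq_fS: float = 0.62
    high_level_frac: float = 0.3
    neutral_sd: float = 0.03
    dosage_slope: float = 1.0
    dispersion: float = 0.1
    base_mean_log: float = 5.0       # natural-log mean of baseline expression
    base_mean_sd: float = 1.0
    lib_size_sd: float = 0.2         # lognormal sd of per-sample depth factor
    mut_rate: float = 60.0           # mean SNVs per sample
    tp53_like_rate: float = 0.89
    signature_mix_R: dict[str, float] = field(default_factory=_default_mix_R)
    signature_mix_fS: dict[str, float] = field(default_factory=_default_mix_fS)

    def __post_init__(self):
        probs = [self.amp_freq_R, self.amp_freq_fS, self.del_freq_R,
                 self.del_freq_fS, self.high_level_frac, self.tp53_like_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for mix in (self.signature_mix_R, self.signature_mix_fS):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("signature exposure vectors must sum to 1")
        if self.n_planted_amp + self.n_planted_del > self.n_genes:
            raise ValueError("more planted genes than genes in the genome")

    @property
    def n_genes(self) -> int:
        return self.n_chrom * self.genes_per_chrom


def recovery_config(seed: int, **overrides) -> GeneratorConfig:
    """High-contrast planted scenario for exact-recovery tests.

    Alteration frequencies are pushed to near-certain vs near-absent so
    the planted genes are identifiable at the cohort's sample size; used
    by the planted-truth recovery suites, not as the cohort default.
    """
    base = dict(amp_freq_R=0.95, amp_freq_fS=0.02,
                del_freq_R=0.02, del_freq_fS=0.95)
    base.update(overrides)
    return GeneratorConfig(seed=seed, **base)


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery."""
    amp_genes: list[str]             # amplified preferentially in R
    del_genes: list[str]             # deleted preferentially in fS
    tp53_like_gene: str
    true_calls: pd.DataFrame         # gene x sample planted call matrix
    true_exposures: pd.DataFrame     # sample x signature mixing weights
    de_effects: pd.Series            # per planted gene: dosage_slope * E[call dif]


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    design: CohortDesign
    gene_models: list[GeneModel]
    segments: list[Segment]
    mutations: list[MutationRecord]
    counts: pd.DataFrame
    catalog: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Write the bundle as plain-text files; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "seg": out / "cohort.seg",
            "maf": out / "cohort.maf",
            "counts": out / "counts.tsv",
            "design": out / "design.tsv",
            "genes": out / "genes.tsv",
            "catalog": out / "signature_catalog.tsv",
            "truth": out / "ground_truth.json",
        }
        write_seg(self.segments, paths["seg"])
        write_maf(self.mutations, paths["maf"])
        write_matrix(self.counts, paths["counts"])
        write_design(self.design, paths["design"])
        write_gene_models(self.gene_models, paths["genes"])
        write_matrix(self.catalog, paths["catalog"])
        truth = {
            "amp_genes": self.truth.amp_genes,
            "del_genes": self.truth.del_genes,
            "tp53_like_gene": self.truth.tp53_like_gene,
        }
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
        return paths


_GENE_SPAN = 5_000
_GENE_PITCH = 10_000


def _build_gene_models(cfg: GeneratorConfig) -> list[GeneModel]:
    genes = []
    for c in range(1, cfg.n_chrom + 1):
        half = cfg.genes_per_chrom // 2
        for i in range(cfg.genes_per_chrom):
            arm = "p" if i < half else "q"
            band_i = (i if arm == "p" else i - half) // cfg.genes_per_cytoband + 1
            start = i * _GENE_PITCH + 1
            genes.append(GeneModel(
                gene_id=f"G{c}_{i + 1:04d}", chrom=str(c),
                start=start, end=start + _GENE_SPAN,
                cytoband=f"{c}{arm}{band_i}",
            ))
    return genes


def _sample_segments(cfg: GeneratorConfig, rng: np.random.Generator,
                     sample: str, genes: list[GeneModel],
                     calls: np.ndarray) -> tuple[list[Segment], np.ndarray]:
    """Tile each chromosome with segments; one log2 level per run of genes
    sharing a call state. Returns segments and the per-gene log2 values."""
    log2 = np.zeros(len(genes))
    segments = []
    i = 0
    while i < len(genes):
        j = i
        while (j + 1 < len(genes) and genes[j + 1].chrom == genes[i].chrom
               and calls[j + 1] == calls[i]):
            j += 1
        state = calls[i]
        if state == 0:
            level = rng.normal(0.0, cfg.neutral_sd)
            level = float(np.clip(level, -0.099, 0.099))
        else:
            high = rng.random() < cfg.high_level_frac
            amp = rng.uniform(1.0, 2.0) if high else rng.uniform(0.15, 0.8)
            level = amp if state > 0 else -amp
        log2[i:j + 1] = level
        segments.append(Segment(
            sample_id=sample, chrom=genes[i].chrom,
            start=genes[i].start, end=genes[j].end,
            log2_ratio=round(level, 6), n_markers=(j - i + 1) * 5,
        ))
        i = j + 1
    return segments, log2


_VARIANT_CLASS_PROBS = {
    "Missense_Mutation": 0.55, "Silent": 0.20, "Nonsense_Mutation": 0.08,
    "Splice_Site": 0.05, "Frame_Shift_Del": 0.04, "Frame_Shift_Ins": 0.03,
    "In_Frame_Del": 0.02, "3'UTR": 0.02, "Intron": 0.01,
}


def _draw_context(rng: np.random.Generator, probs96: np.ndarray) -> tuple[str, str, str]:
    """Draw a 96-bin and return (ref, alt, pyrimidine-strand context)."""
    b = rng.choice(96, p=probs96)
    label = SPECTRUM_CONTEXTS[b]
    five, sub, three = label[0], label[2:5], label[6]
    ref, alt = sub[0], sub[2]
    return ref, alt, f"{five}{ref}{three}"


def generate_cohort(config: GeneratorConfig, out_dir=None) -> SyntheticCohort:
    """Generate the full synthetic bundle; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _build_gene_models(cfg)
    gene_ids = [g.gene_id for g in genes]
    samples = [f"R{i + 1:02d}" for i in range(cfg.n_R)] + \
              [f"S{i + 1:02d}" for i in range(cfg.n_fS)]
    classes = ["R"] * cfg.n_R + ["fS"] * cfg.n_fS
    design = CohortDesign(dict(zip(samples, classes)))
    catalog = synthetic_signature_catalog()

    # planted gene positions: interleave amp and del blocks away from each other
    order = rng.permutation(cfg.n_genes)
    amp_idx = np.sort(order[: cfg.n_planted_amp])
    del_idx = np.sort(order[cfg.n_planted_amp: cfg.n_planted_amp + cfg.n_planted_del])
    amp_genes = [gene_ids[i] for i in amp_idx]
    del_genes = [gene_ids[i] for i in del_idx]

    # copy number
    calls = np.zeros((cfg.n_genes, len(samples)), dtype=int)
    all_segments: list[Segment] = []
    log2_true = np.zeros_like(calls, dtype=float)
    for j, (sample, cls) in enumerate(zip(samples, classes)):
        p_amp = cfg.amp_freq_R if cls == "R" else cfg.amp_freq_fS
        p_del = cfg.del_freq_R if cls == "R" else cfg.del_freq_fS
        col = np.zeros(cfg.n_genes, dtype=int)
        col[amp_idx] = rng.random(amp_idx.size) < p_amp
        col[del_idx] = -(rng.random(del_idx.size) < p_del).astype(int)
        segs, lv = _sample_segments(cfg, rng, sample, genes, col)
        # refine planted calls by amplitude (high-level events are +-2)
        col_refined = np.zeros_like(col)
        col_refined[np.abs(lv) >= 0.1] = np.sign(lv[np.abs(lv) >= 0.1])
        col_refined[np.abs(lv) >= 0.9] = 2 * np.sign(lv[np.abs(lv) >= 0.9])
        calls[:, j] = col_refined
        log2_true[:, j] = lv
        all_segments.extend(segs)

    # expression: NB counts, mean scaled by 2^(slope * call) and depth factor
    base_mean = np.exp(rng.normal(cfg.base_mean_log, cfg.base_mean_sd, cfg.n_genes))
    depth = np.exp(rng.normal(0.0, cfg.lib_size_sd, len(samples)))
    mean = base_mean[:, None] * (2.0 ** (cfg.dosage_slope * calls)) * depth[None, :]
    r_nb = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mean))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples)

    # mutations
    tp53_like = gene_ids[0]
    sig_names = list(catalog.columns)
    mix_by_class = {}
    for cls, mix in (("R", cfg.signature_mix_R), ("fS", cfg.signature_mix_fS)):
        w = np.zeros(len(sig_names))
        for name, v in mix.items():
            w[sig_names.index(name)] = v
        mix_by_class[cls] = (w, catalog.to_numpy() @ w)
    mutations: list[MutationRecord] = []
    exposures = {}
    class_order = list(_VARIANT_CLASS_PROBS)
    class_p = np.array(list(_VARIANT_CLASS_PROBS.values()))
    class_p = class_p / class_p.sum()
    for sample, cls in zip(samples, classes):
        w, probs96 = mix_by_class[cls]
        exposures[sample] = pd.Series(w, index=sig_names)
        n_snv = rng.poisson(cfg.mut_rate)
        for _ in range(n_snv):
            ref, alt, ctx = _draw_context(rng, probs96)
            gi = int(rng.integers(0, cfg.n_genes))
            g = genes[gi]
            pos = int(rng.integers(g.start + 1, g.end))  # keep flanks inside
            vclass = class_order[int(rng.choice(len(class_order), p=class_p))]
            mutations.append(MutationRecord(
                sample_id=sample, gene_id=g.gene_id, chrom=g.chrom, pos=pos,
                ref_allele=ref, alt_allele=alt, variant_class=vclass,
                trinucleotide_context=ctx))
        if rng.random() < cfg.tp53_like_rate:
            g = genes[0]
            ref, alt, ctx = _draw_context(rng, probs96)
            mutations.append(MutationRecord(
                sample_id=sample, gene_id=tp53_like, chrom=g.chrom,
                pos=int(rng.integers(g.start + 1, g.end)),
                ref_allele=ref, alt_allele=alt,
                variant_class="Nonsense_Mutation", trinucleotide_context=ctx))

    true_calls = pd.DataFrame(calls, index=pd.Index(gene_ids, name="gene_id"),
                              columns=samples)
    mean_call_R = true_calls[design.samples("R")].mean(axis=1)
    mean_call_fS = true_calls[design.samples("fS")].mean(axis=1)
    de_effects = (cfg.dosage_slope * (mean_call_R - mean_call_fS))[
        true_calls.index.isin(amp_genes + del_genes)]
    truth = GroundTruth(
        amp_genes=amp_genes, del_genes=del_genes, tp53_like_gene=tp53_like,
        true_calls=true_calls, true_exposures=pd.DataFrame(exposures).T,
        de_effects=de_effects,
    )
    cohort = SyntheticCohort(config=cfg, design=design, gene_models=genes,
                             segments=all_segments, mutations=mutations,
                             counts=counts_df, catalog=catalog, truth=truth)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def generate_null_cohort(config: GeneratorConfig, out_dir=None) -> SyntheticCohort:
    """Same machinery with every class-conditional parameter equalized.

    Both classes get the average alteration frequencies and signature
    mixture, so any detected class difference is a false positive; used by
    the type-I-error suites.
    """
    mix_r, mix_f = config.signature_mix_R, config.signature_mix_fS
    keys = sorted(set(mix_r) | set(mix_f))
    mix = {k: 0.5 * (mix_r.get(k, 0.0) + mix_f.get(k, 0.0)) for k in keys}
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    null_cfg = replace(
        config,
        amp_freq_R=0.5 * (config.amp_freq_R + config.amp_freq_fS),
        amp_freq_fS=0.5 * (config.amp_freq_R + config.amp_freq_fS),
        del_freq_R=0.5 * (config.del_freq_R + config.del_freq_fS),
        del_freq_fS=0.5 * (config.del_freq_R + config.del_freq_fS),
        signature_mix_R=mix, signature_mix_fS=mix,
    )
    return generate_cohort(null_cfg, out_dir=out_dir)
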