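"""Somatic copy-number analysis.

Segment-to-gene thresholded calls, G-score recurrence with a permutation
null, per-sample genomic-instability metrics, and binarized amp/del
class-association tests.

The G score of a gene in one direction is its alteration frequency across
samples times the mean altered amplitude (frequency x amplitude). The
significance null permutes the gene axis of each sample's log2 vector
independently, pooling null scores over genes and permutations — a
deliberate simplification of marker-based background models; no peel-off
of secondary peaks is attempted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics_io import CohortDesign, GeneModel, Segment
from .stats import bh_qvalues, fisher_exact, odds_ratio, rank_sum_test

__all__ = [
    "GeneCallMatrix", "GScoreTrack", "RecurrentRegion",
    "calls_from_segments", "g_scores", "recurrent_regions",
    "binarize", "instability", "compare_instability", "class_association",
    "DEFAULT_LOW_THR", "DEFAULT_HIGH_THR",
]

DEFAULT_LOW_THR = 0.1
DEFAULT_HIGH_THR = 0.9


@dataclass
class GeneCallMatrix:
    """Gene x sample continuous log2 values and thresholded calls.

    Calls live in {-2, -1, 0, 1, 2}: 0 when |log2| < low threshold,
    +-1 for low-level gain/loss, +-2 beyond the high threshold.
    Genes are kept in genome order (chrom, start).
    """
    genes: list[GeneModel]
    samples: list[str]
    log2: np.ndarray   # (n_genes, n_samples), float
    call: np.ndarray   # (n_genes, n_samples), int

    def __post_init__(self):
        if self.log2.shape != (len(self.genes), len(self.samples)):
            raise ValueError("log2 matrix shape inconsistent with genes/samples")
        if self.call.shape != self.log2.shape:
            raise ValueError("call matrix shape inconsistent with log2")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def log2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log2, index=self.gene_ids, columns=self.samples)

    def call_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.call, index=self.gene_ids, columns=self.samples)


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def calls_from_segments(
    segments: list[Segment],
    gene_models: list[GeneModel],
    low_thr: float = DEFAULT_LOW_THR,
    high_thr: float = DEFAULT_HIGH_THR,
    samples: list[str] | None = None,
) -> GeneCallMatrix:
    """Reduce segmented profiles to per-gene log2 values and calls.

    A gene's log2 value is the overlap-length-weighted mean of the log2
    ratios of all segments it intersects; a gene with no overlapping
    segment gets log2 = 0 and call = 0.
    """
    if not gene_models:
        raise ValueError("empty gene model")
    if not (0 < low_thr < high_thr):
        raise ValueError("need 0 < low_thr < high_thr")
    genes = sorted(gene_models, key=lambda g: (_chrom_sort_key(g.chrom), g.start))
    if samples is None:
        samples = sorted({s.sample_id for s in segments})
    sample_idx = {s: i for i, s in enumerate(samples)}

    genes_by_chrom: dict[str, list[tuple[int, GeneModel]]] = defaultdict(list)
    for i, g in enumerate(genes):
        genes_by_chrom[g.chrom].append((i, g))

    wsum = np.zeros((len(genes), len(samples)))
    lsum = np.zeros_like(wsum)
    for seg in segments:
        j = sample_idx.get(seg.sample_id)
        if j is None:
            continue
        for i, g in genes_by_chrom.get(seg.chrom, ()):
            if g.start > seg.end:
                break
            ov = min(g.end, seg.end) - max(g.start, seg.start) + 1
            if ov > 0:
                wsum[i, j] += ov * seg.log2_ratio
                lsum[i, j] += ov
        # genes are sorted by start; once a gene starts past the segment end
        # no later gene on the chromosome can overlap, hence the break above

    log2 = np.divide(wsum, lsum, out=np.zeros_like(wsum), where=lsum > 0)
    call = np.zeros(log2.shape, dtype=int)
    call[log2 >= low_thr] = 1
    call[log2 >= high_thr] = 2
    call[log2 <= -low_thr] = -1
    call[log2 <= -high_thr] = -2
    # strict: |log2| < low_thr -> 0 (>= low_thr qualifies as altered)
    return GeneCallMatrix(genes=genes, samples=list(samples), log2=log2, call=call)


@dataclass
class GScoreTrack:
    """Per-gene recurrence scores for one direction (amp or del)."""
    direction: str
    gene_ids: list[str]
    freq: np.ndarray
    mean_amp: np.ndarray
    g: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_perm: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "direction": self.direction, "freq": self.freq,
            "mean_amp": self.mean_amp, "g_score": self.g,
            "p": self.p, "q": self.q,
        }, index=pd.Index(self.gene_ids, name="gene_id"))


def _g_stat(a: np.ndarray, low_thr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    alt = a > low_thr
    n = alt.sum(axis=1)
    freq = n / a.shape[1]
    amp_sum = np.where(alt, a, 0.0).sum(axis=1)
    mean_amp = np.divide(amp_sum, n, out=np.zeros(a.shape[0]), where=n > 0)
    return freq, mean_amp, freq * mean_amp


def g_scores(
    matrix: GeneCallMatrix | np.ndarray,
    direction: str,
    low_thr: float = DEFAULT_LOW_THR,
    n_perm: int = 1000,
    seed: int | None = None,
    gene_ids: list[str] | None = None,
) -> GScoreTrack:
    """G = frequency x mean amplitude per gene, with a permutation p-value.

    The null shuffles each sample's log2 vector along the gene axis
    independently (seeded) and pools the resulting null G values over all
    genes and permutations:
    p(g) = (1 + #{null G >= G_obs}) / (1 + n_perm * n_genes).
    Deletions are scored symmetrically on -log2.
    """
    if direction not in ("amp", "del"):
        raise ValueError(f"direction must be 'amp' or 'del', got {direction!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(matrix, GeneCallMatrix):
        log2 = matrix.log2
        gene_ids = matrix.gene_ids
    else:
        log2 = np.asarray(matrix, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(log2.shape[0])]
    a = log2 if direction == "amp" else -log2
    freq, mean_amp, g_obs = _g_stat(a, low_thr)

    rng = np.random.default_rng(seed)
    n_genes, n_samples = a.shape
    null = np.empty(n_perm * n_genes)
    for k in range(n_perm):
        perm = np.argsort(rng.random((n_genes, n_samples)), axis=0)
        a_perm = np.take_along_axis(a, perm, axis=0)
        null[k * n_genes:(k + 1) * n_genes] = _g_stat(a_perm, low_thr)[2]
    null.sort()
    n_null = null.size
    ge = n_null - np.searchsorted(null, g_obs, side="left")
    p = (1.0 + ge) / (1.0 + n_null)
    q = bh_qvalues(p)
    return GScoreTrack(direction=direction, gene_ids=list(gene_ids), freq=freq,
                       mean_amp=mean_amp, g=g_obs, p=p, q=q, n_perm=n_perm)


@dataclass
class RecurrentRegion:
    """A maximal run of contiguous genes passing the FDR cut."""
    direction: str
    chrom: str
    start_index: int
    end_index: int           # inclusive, indices into the genome-ordered gene list
    gene_ids: list[str]
    cytobands: list[str]     # ordered, deduplicated span
    peak_q: float


def recurrent_regions(
    track: GScoreTrack,
    genes: list[GeneModel],
    fdr_cut: float = 0.1,
) -> list[RecurrentRegion]:
    """Maximal contiguous runs (genome order, per chromosome) with q < cut."""
    if len(genes) != len(track.gene_ids):
        raise ValueError("gene model list does not match the score track")
    regions: list[RecurrentRegion] = []
    run: list[int] = []

    def flush():
        if run:
            members = [genes[i] for i in run]
            regions.append(RecurrentRegion(
                direction=track.direction, chrom=members[0].chrom,
                start_index=run[0], end_index=run[-1],
                gene_ids=[g.gene_id for g in members],
                cytobands=list(dict.fromkeys(g.cytoband for g in members)),
                peak_q=float(min(track.q[i] for i in run)),
            ))
            run.clear()

    for i, g in enumerate(genes):
        passing = track.q[i] < fdr_cut
        if passing and run and genes[run[-1]].chrom != g.chrom:
            flush()
        if passing:
            run.append(i)
        else:
            flush()
    flush()
    return regions


def binarize(call: np.ndarray | pd.DataFrame, direction: str):
    """1 iff altered in the given direction; deletions do not count as amplified."""
    if direction == "amp":
        out = (call > 0)
    elif direction == "del":
        out = (call < 0)
    else:
        raise ValueError(f"direction must be 'amp' or 'del', got {direction!r}")
    return out.astype(int)


def instability(segments: list[Segment], matrix: GeneCallMatrix) -> pd.DataFrame:
    """Per-sample genomic-instability metrics.

    n_segments: rows in the segmented profile; n_amplified_genes /
    n_deleted_genes: genes with positive / negative calls; n_altered_genes
    is their sum.
    """
    seg_counts: dict[str, int] = defaultdict(int)
    for s in segments:
        seg_counts[s.sample_id] += 1
    amp = (matrix.call > 0).sum(axis=0)
    dele = (matrix.call < 0).sum(axis=0)
    return pd.DataFrame({
        "n_segments": [seg_counts.get(s, 0) for s in matrix.samples],
        "n_amplified_genes": amp,
        "n_deleted_genes": dele,
        "n_altered_genes": amp + dele,
    }, index=pd.Index(matrix.samples, name="sample_id"))


def compare_instability(profile: pd.DataFrame, design: CohortDesign) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per instability metric (R vs fS)."""
    r = [s for s in profile.index if design[s] == "R"]
    fs = [s for s in profile.index if design[s] == "fS"]
    return pd.Series({m: rank_sum_test(profile.loc[r, m], profile.loc[fs, m])
                      for m in profile.columns}, name="wilcoxon_p")


def class_association(
    binary: pd.DataFrame,
    design: CohortDesign,
    direction: str | None = None,
) -> pd.DataFrame:
    """Fisher exact association of each binary unit (gene/region/pathway)
    with the sensitivity class.

    ``binary`` is a unit x sample 0/1 matrix. Returns one row per unit with
    the 2x2 table (a, b: altered/not in R; c, d: altered/not in fS), odds
    ratio (infinite reported as inf), two-sided Fisher p, BH q across all
    units, per-class alteration frequencies and the favored class (the one
    with the higher alteration frequency). Units altered in zero samples
    get p = 1 and are flagged degenerate.
    """
    r = [s for s in binary.columns if design[s] == "R"]
    fs = [s for s in binary.columns if design[s] == "fS"]
    if not r or not fs:
        raise ValueError("both classes must be represented among the samples")
    rows = []
    vals = binary.astype(bool)
    for unit in binary.index:
        a = int(vals.loc[unit, r].sum())
        c = int(vals.loc[unit, fs].sum())
        b, d = len(r) - a, len(fs) - c
        degenerate = (a + c) == 0
        p = 1.0 if degenerate else fisher_exact(a, b, c, d)
        freq_r, freq_fs = a / len(r), c / len(fs)
        if freq_r > freq_fs:
            favored = "R"
        elif freq_fs > freq_r:
            favored = "fS"
        else:
            favored = "none"
        rows.append({
            "unit_id": unit, "direction": direction, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds_ratio(a, b, c, d), "p": p,
            "freq_R": freq_r, "freq_fS": freq_fs,
            "favored_class": favored, "degenerate": degenerate,
        })
    out = pd.DataFrame(rows).set_index("unit_id")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out
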