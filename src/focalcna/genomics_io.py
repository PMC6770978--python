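"""Readers/writers for the on-disk formats and the canonical in-memory tables.

Formats handled: SEG (Broad dialect, tab-separated), MAF (TCGA dialect,
minimal column set), GMT gene-set collections, TSV numeric matrices, the
two-column sample design file, and a BED-like gene model table with
cytobands.

Conventions
-----------
* All genomic intervals are 1-based and fully closed, matching SEG.
* Chromosome names are normalized to their canonical form without a
  leading "chr"; X and Y are kept as letters. Normalization is idempotent.
* Readers never filter biologically (e.g. silent variants are retained);
  filtering is the job of downstream modules.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "Segment", "GeneModel", "MutationRecord", "CohortDesign",
    "FormatError",
    "normalize_chrom",
    "read_seg", "write_seg",
    "read_maf", "write_maf",
    "read_gmt", "write_gmt",
    "read_matrix", "write_matrix",
    "read_design", "write_design",
    "read_gene_models", "write_gene_models",
]

#: Standard MAF Variant_Classification vocabulary. Unknown values are
#: preserved at IO level and mapped to impact "unknown" downstream.
MAF_VARIANT_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Silent", "Splice_Site", "Translation_Start_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron", "IGR", "RNA",
    "Targeted_Region",
})


class FormatError(ValueError):
    """A file violates its format contract (bad field, bad invariant)."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class Segment:
    """One sample's contiguous genomic interval with a log2 copy-ratio."""
    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_markers: int | None = None

    def __post_init__(self):
        if self.start < 1:
            raise FormatError(f"segment start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise FormatError(
                f"segment end {self.end} precedes start {self.start}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    cytoband: str

    def __post_init__(self):
        if self.end < self.start:
            raise FormatError(f"gene {self.gene_id}: end precedes start")
        if not self.cytoband:
            raise FormatError(f"gene {self.gene_id}: empty cytoband")


@dataclass(frozen=True)
class MutationRecord:
    """A somatic variant row (MAF semantics, 1-based position)."""
    sample_id: str
    gene_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    trinucleotide_context: str | None = None

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise FormatError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}")
        ctx = self.trinucleotide_context
        if ctx is not None and len(ctx) != 3:
            raise FormatError(f"trinucleotide context must have length 3: {ctx!r}")

    @property
    def is_snv(self) -> bool:
        return (len(self.ref_allele) == 1 and len(self.alt_allele) == 1
                and self.ref_allele in "ACGT" and self.alt_allele in "ACGT")


class CohortDesign:
    """sample -> class label mapping for a two-class (R vs fS) cohort."""

    CLASSES = ("R", "fS")

    def __init__(self, labels: dict[str, str]):
        bad = {s: c for s, c in labels.items() if c not in self.CLASSES}
        if bad:
            raise FormatError(f"class labels must be in {self.CLASSES}: {bad}")
        self.labels = dict(labels)
        if self.n_R < 1 or self.n_fS < 1:
            raise FormatError("both classes must contain at least one sample")

    def samples(self, cls: str | None = None) -> list[str]:
        if cls is None:
            return list(self.labels)
        return [s for s, c in self.labels.items() if c == cls]

    @property
    def n_R(self) -> int:
        return sum(1 for c in self.labels.values() if c == "R")

    @property
    def n_fS(self) -> int:
        return sum(1 for c in self.labels.values() if c == "fS")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, sample: str) -> str:
        return self.labels[sample]

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortDesign) and self.labels == other.labels


# ---------------------------------------------------------------------------
# SEG

def _check_no_overlap(segments: list[Segment]) -> None:
    by_key: dict[tuple[str, str], list[Segment]] = defaultdict(list)
    for s in segments:
        by_key[(s.sample_id, s.chrom)].append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise FormatError(
                    f"overlapping segments for sample {sample} on chromosome "
                    f"{chrom}: [{prev.start},{prev.end}] and [{cur.start},{cur.end}]")


def read_seg(path) -> list[Segment]:
    """Read a Broad-dialect SEG file (header + >= 6 tab-separated columns).

    Columns: sample, chromosome, start, end, num-markers, segment-mean.
    A missing/blank num-markers field is allowed and stored as None.
    Rows are returned sorted by (sample, chrom, start); overlapping
    segments within one sample and chromosome raise :class:`FormatError`.
    """
    segments: list[Segment] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path} line {lineno}: expected >= 6 columns, got {len(fields)}")
            sample, chrom, start_s, end_s, nm_s, mean_s = fields[:6]
            try:
                start, end = int(float(start_s)), int(float(end_s))
                log2 = float(mean_s)
                n_markers = int(float(nm_s)) if nm_s.strip() not in ("", "NA") else None
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: malformed numeric field ({exc})") from None
            try:
                segments.append(Segment(sample_id=sample, chrom=normalize_chrom(chrom),
                                        start=start, end=end, log2_ratio=log2,
                                        n_markers=n_markers))
            except FormatError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from None
    _check_no_overlap(segments)
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    return segments


def write_seg(segments: Iterable[Segment], path) -> None:
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for s in segments:
            nm = "" if s.n_markers is None else str(s.n_markers)
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{nm}\t{s.log2_ratio:.6g}\n")


# ---------------------------------------------------------------------------
# MAF

_MAF_REQUIRED = ["Hugo_Symbol", "Chromosome", "Start_Position",
                 "Reference_Allele", "Tumor_Seq_Allele2",
                 "Variant_Classification", "Tumor_Sample_Barcode"]
_MAF_CONTEXT = "Trinucleotide_Context"


def read_maf(path) -> list[MutationRecord]:
    """Read a minimal-column TCGA-dialect MAF; '#' comment lines skipped."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required MAF column(s): {', '.join(missing)}")
    records = []
    has_ctx = _MAF_CONTEXT in df.columns
    for row in df.itertuples(index=False):
        ctx = getattr(row, _MAF_CONTEXT, None) if has_ctx else None
        if isinstance(ctx, float) or ctx in (None, "", "NA"):
            ctx = None
        records.append(MutationRecord(
            sample_id=row.Tumor_Sample_Barcode,
            gene_id=row.Hugo_Symbol,
            chrom=normalize_chrom(row.Chromosome),
            pos=int(row.Start_Position),
            ref_allele=row.Reference_Allele,
            alt_allele=row.Tumor_Seq_Allele2,
            variant_class=row.Variant_Classification,
            trinucleotide_context=ctx,
        ))
    return records


def write_maf(records: Iterable[MutationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MAF_REQUIRED + [_MAF_CONTEXT]) + "\n")
        for r in records:
            ctx = r.trinucleotide_context or ""
            fh.write("\t".join([r.gene_id, r.chrom, str(r.pos), r.ref_allele,
                                r.alt_allele, r.variant_class, r.sample_id, ctx]) + "\n")


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes.

    Duplicate members within a set are deduplicated (first occurrence
    order kept); duplicate set names raise :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT line needs name, description and >= 1 gene")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path} line {lineno}: duplicate gene-set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices, design, gene models

def read_matrix(path) -> pd.DataFrame:
    """Read a gene x sample numeric TSV (first column: unique gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene ID(s): {dups[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a gene x sample matrix; lossless round trip at 10 significant digits."""
    df.to_csv(path, sep="\t", float_format=float_format)


def read_design(path) -> CohortDesign:
    """Read a two-column (sample_id, class) TSV into a :class:`CohortDesign`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: design file needs sample_id and class columns")
    sample_col, class_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        raise FormatError(f"{path}: duplicated sample IDs in design file")
    return CohortDesign(dict(zip(df[sample_col], df[class_col])))


def write_design(design: CohortDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for s, c in design.labels.items():
            fh.write(f"{s}\t{c}\n")


def read_gene_models(path) -> list[GeneModel]:
    """Read the gene model TSV: gene_id, chrom, start, end, cytoband.

    Coordinates are 1-based closed (SEG convention). BED-derived inputs
    must be shifted by +1 on the start before use; this loader does not
    guess the convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "cytoband": str})
    required = ["gene_id", "chrom", "start", "end", "cytoband"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene-model column(s): {', '.join(missing)}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated gene IDs")
    return [GeneModel(gene_id=r.gene_id, chrom=normalize_chrom(r.chrom),
                      start=int(r.start), end=int(r.end), cytoband=r.cytoband)
            for r in df.itertuples(index=False)]


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tcytoband\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.cytoband}\n")
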