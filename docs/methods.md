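# Methods

`focalcna` implements an integrated somatic copy-number / mutation /
expression analysis for a two-class tumor cohort: platinum-**R**esistant
versus frankly **S**ensitive (fS) completely debulked high-grade serous
ovarian cancer patients, the archetypal copy-number-driven tumor. The
package takes segmented copy-number profiles (SEG), somatic variants
(MAF), raw RNA-seq counts and a two-column sample design, and produces
gene-level alteration calls, recurrence scores, class-association tests,
mutational-signature exposures, differential expression and, at the end
of the chain, the list of genes whose copy-number imbalance between the
classes is concordant with their expression change. A seeded synthetic
cohort generator with planted ground truth makes every stage testable at
desk scale.

## Copy-number analysis

**Gene-level calls.** Each gene's log2 copy-ratio is the
overlap-length-weighted mean of the segments it intersects; a gene with
no overlapping segment is neutral. The continuous value is thresholded
into calls {−2, −1, 0, +1, +2} at |log2| ≥ `low_thr` (default 0.1,
low-level event) and |log2| ≥ `high_thr` (default 0.9, high-level
event). These cutoffs mirror the conventional thresholded-call semantics
of GISTIC-style pipelines but are deliberately fixed rather than
sample-adaptive; both are configurable. The weighted-mean reduction is a
design choice of this package (deterministic, marker-free) — upstream
callers that emit marker counts are not required.

**Recurrence (G score).** For direction amp, a gene's score is
G = f · ā where f is the fraction of samples with log2 > `low_thr` and ā
the mean of those positive log2 values (deletions are scored on −log2).
Significance comes from a within-sample gene-permutation null: each
sample's log2 vector is shuffled along the gene axis, G is recomputed,
and null scores are pooled over all genes and `n_perm` permutations;
p(g) = (1 + #{null ≥ G(g)}) / (1 + n_perm · n_genes), with BH correction
across genes. This replaces the semi-exact marker-based background model
of the original recurrence machinery with an explicitly documented
permutation null; peel-off of secondary peaks is not implemented.
Recurrent regions are maximal runs of contiguous genes (genome order,
per chromosome) with q below the FDR cut (default 0.1), annotated with
their cytoband span.

**Instability and association.** Per sample we count segments, amplified
genes, deleted genes and their sum; class differences are tested by
two-sided Wilcoxon rank-sum. Amplifications and deletions are binarized
separately (a deleted gene is *not* "not amplified" in the deletion
analysis — it is the event of interest) and each gene/region/pathway is
tested against the class in a 2×2 Fisher exact test with BH correction.
Infinite odds ratios are reported as such, never clipped.

## Exact 2×2 statistics

Fisher p-values are computed in exact integer arithmetic on the
hypergeometric support (numerators compared as integers, one float
conversion at the end), so oracle tests can demand agreement to 1e−12.
Two two-sided conventions are provided:

* **minlike** (default for association testing): the classical
  definition — the probability of all tables no more likely than the one
  observed; identical to R's `fisher.test`.
* **central**: twice the smaller one-sided tail, capped at 1 — the
  convention used by central exact 2×2 tests and the power/sample-size
  routines built on them.

BH q-values are the textbook step-up (q ≥ p enforced against 1-ulp float
shortfall). The Wilcoxon rank-sum test uses the exact null distribution
when there are no ties and combined n ≤ 30 (the cohort regime), and the
tie-corrected normal approximation otherwise.

## Statistical power of the screen (`design`)

The exact power of the per-gene two-sided Fisher test is computed by
full binomial enumeration:

    power = Σ_x Σ_y  Bin(x; n1, p1) · Bin(y; n2, p2) · 1[p(x, y) ≤ α]

"At least one significant finding at FDR f over m tests" is
operationalized as the per-test level α = f / m — the BH step-up's
first-step threshold when a single hypothesis is non-null. With the
cohort's observed rates (p1 = 0.27, p2 = 0.94, n = 11 vs 16, m = 20 000,
f = 0.05) the power is 2.4% under the **central** two-sided convention,
and the smallest equal group size reaching 80% power is 31. The central
convention is the default here because it is what the established exact
2×2 power routines compute; under the minlike convention the same screen
has power 7.1% (α is so small that the doubled-tail and minimum-likelihood
rejection regions differ materially at these unbalanced sizes). Both are
available via `method=`.

## Mutation analysis

Variant impact is a configurable mapping from MAF
`Variant_Classification` to {high, moderate, low, modifier, unknown};
the disruptive filter keeps high/moderate (truncating, splice,
frameshift, start/stop events are high; missense and in-frame indels
moderate). Unknown classes are preserved at IO and excluded by the
filter. Mutational load is counted per sample in "all" or "disruptive"
mode and compared between classes by rank-sum. Pathways are flagged
mutated in a sample if at least one member gene carries a mutation, then
tested like any binary unit.

**Spectra and signatures.** SNVs are folded onto the pyrimidine strand
(purine-reference events reverse-complemented, flanks included), giving
a 96-bin count vector per sample in a fixed substitution-major order.
Exposures to a column-stochastic signature catalog are fitted by forward
selection: normalize the spectrum to proportions, repeatedly add the
signature whose inclusion most reduces the squared reconstruction error
under non-negative weights summing to ≤ 1, stop when the relative error
improvement drops below `improvement_tol` (default 1e−3), then zero
weights below `retention_cutoff` (default 0.06) and re-fit on the
retained support until stable. The defaults follow the published
defaults of the standard deconvolution tool this procedure mirrors. The
inner solver is NNLS; the sum constraint, rarely active for probability
inputs, is enforced by a weighted penalty row with a final exact
renormalization. De-novo extraction (NMF) and indel/DBS signatures are
out of scope. Samples are clustered on their top-5 signatures
(Euclidean distance, Ward linkage) and the 2-cluster cut is tested
against the class by Fisher exact.

The bundled catalog (`simulate.synthetic_signature_catalog`) is a
**synthetic** 96×30 column-stochastic matrix (sparse Dirichlet draws,
fixed seed) used by the generator and the tests; analyses of real
cohorts should supply the COSMIC v2 TSV, which is not bundled.

## Expression analysis

**TMM.** Scaling factors follow the trimmed-mean-of-M-values algorithm:
reference sample = the one whose CPM upper quartile is closest to the
mean upper quartile; per gene, M = log-ratio and A = log-abundance
against the reference (zero counts excluded); doubly trim (30% on M, 5%
on A, rank-based); average surviving M values weighted by inverse
asymptotic binomial variances; rescale factors to geometric mean 1. The
implementation reproduces the Bioconductor reference to ≤ 1e−6 on test
fixtures (cross-checked through Rscript). Note the inverse-variance
weights make factors only *approximately* invariant to rescaling a
single library (~1% at a few hundred genes); the unweighted identity is
exact.

**Filtering and DE.** Genes are kept if CPM ≥ 1 in at least ⌈5% of
samples⌉ (both configurable). Differential expression is a moderated
two-sample t on log2-CPM (prior count 0.5): the pooled per-gene variance
is shrunk toward the cohort-mean variance with weight `shrink` (default
0.1); p-values use t with n1+n2−2 df. This deliberately replaces the
precision-weighted linear-model pipeline commonly used for this step:
only the log fold-change and the nominal p feed the downstream
concordance filter, and the simpler statistic is exactly checkable
against a plain t-test at `shrink = 0`. The substitution is a documented
design decision, and the null calibration of the moderated test is
verified by simulation (type-I error within [0.03, 0.07] at nominal
0.05 on 9-vs-14 null cohorts). Whether fold-changes should be computed
on precision-weighted values was an open choice; this package defines
log2FC on plain TMM log-CPM.

**Enrichment.** Pre-ranked GSEA uses the classical weighted
Kolmogorov–Smirnov running sum (weight exponent 1) on the moderated t
ranking; the null permutes gene labels (seeded), p is one-sided among
same-sign null scores, NES divides by the mean same-sign |null ES|. A
set spanning the entire ranked universe has no miss steps; its ES is
defined as 0. Over-representation is the hypergeometric upper tail on a
user-supplied universe. Gene-set collections come from user GMTs; none
are bundled.

## The concordance decision tree (`integration`)

Four ordered, monotone filters join copy number to expression:

1. keep genes with nominal Fisher p < 0.05 in the amp or del
   class-association (nominal, not FDR-adjusted, because at this cohort
   size no gene survives correction — the q-value is still reported);
2. drop genes not assessed by RNA-seq;
3. assign each gene to the class with the strictly higher alteration
   frequency (the strict-inequality reading of "compared relative
   frequencies" is this package's formalization; an optional minimum
   frequency difference, default 0, tightens it); genes with equal
   frequencies, or significant in both directions with tied p, are
   dropped and logged;
4. keep genes whose log2FC direction matches the copy-number direction
   in the favored class (amplified-in-X ⇒ up in X; deleted-in-X ⇒ down
   in X) and |log2FC| ≥ 0.5.

Cytoband summaries report, per alteration type, the relative frequency
of each cytoband among selected genes. `run_pipeline` orchestrates all
stages from a YAML config, writes every stage table as TSV plus a
machine-readable `summary.json` (per-step gene counts, parameters,
seed), and is byte-deterministic given the seed.

## Synthetic cohorts (`simulate`)

The generator emulates the study's class structure at desk scale:

* **Cohort**: 11 R vs 16 fS samples; genome of 2 chromosomes × 500
  genes (10 kb pitch, 5 kb genes, 25-gene cytobands) so the full
  pipeline runs in seconds; all sizes configurable.
* **Copy number**: 50 planted amplification genes altered per sample
  with probability 0.57 (R) vs 0.12 (fS), and 50 planted deletion genes
  at 0.15 (R) vs 0.62 (fS) — the cohort's reported median per-class
  alteration frequencies among class-associated genes. Altered runs
  draw a low-level amplitude (uniform 0.15–0.8) or, with probability
  0.3, a high-level one (uniform 1.0–2.0) — a modeling choice, not an
  estimate; neutral runs get N(0, 0.03) jitter. Runs of genes sharing a
  state merge into segments.
* **Expression**: negative-binomial counts (dispersion 0.1, lognormal
  baseline means and depth factors) with the gene mean scaled by
  2^(dosage_slope · call), dosage_slope default 1 (direct dosage).
* **Mutations**: per sample, Poisson(60) SNVs with trinucleotide
  contexts drawn from the class's signature mixture over the synthetic
  catalog — R: 0.55/0.15/0.30 and fS: 0.25/0.45/0.30 on Signatures
  1/3/5, i.e. a 0.30 exposure shift between the clock-like and HRD-like
  components; and a designated TP53-like gene carrying a truncating
  mutation in 89% of samples. Mean SNV count 60 is a realistic exome
  order of magnitude for this tumor type.
* **Null cohorts** equalize every class-conditional parameter (averaged
  across classes) for type-I-error suites.

Everything is driven by one `numpy` Generator seed; identical seeds
yield byte-identical files.

**What the generator does not emulate**: marker-level segmentation
noise, arm-level versus focal interplay, subclonal mixtures, GC/length
biases in counts, indel signatures, and correlated gene-gene expression
structure. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated model, not performance on real
tumor data.

**Recovery scenario.** At the default (cohort-realistic) alteration
frequencies, the exact per-gene Fisher power at nominal 0.05 with 11 vs
16 samples is ≈ 0.66 in each direction — computable with
`focalcna.design.fisher_power` — which bounds any selection's recall at
those settings; this is precisely the underpowering the power analysis
quantifies. Planted-truth recovery tests therefore use
`simulate.recovery_config` (alteration probabilities 0.95 vs 0.02),
under which the selection recovers the planted set with precision and
recall ≥ 0.9; dosage-slope recovery and all calibration suites run at
the defaults.

## Numerical and degenerate-input choices

* Coordinates are 1-based fully closed (SEG convention); BED-style
  inputs must be shifted at the boundary. Chromosome names are
  normalized by stripping a leading "chr" (idempotent); X/Y stay
  letters.
* Overlapping segments within one sample/chromosome are rejected at
  load rather than resolved by a guessed tie-break.
* Units altered in zero samples get Fisher p = 1 and a degenerate flag.
* A gene covered by no segment is neutral, not missing.
* An empty concordant selection yields empty cytoband summaries (no
  division by zero).
* Signature fitting requires a spectrum with ≥ 1 mutation and a
  column-stochastic catalog (columns sum to 1 within 1e−6).
* All permutation machinery (G score, GSEA) takes explicit seeds;
  p-values use the (1 + exceedances) / (1 + draws) estimator and are
  therefore never 0.

## Problem sizes used by the test suites

Replicate-based suites run at deliberately small sizes chosen so the
whole suite completes in about a minute while keeping binomial/KS
margins comfortable: 50 replicates for null-calibration and
class-shift detection checks, 20 seeds for planted-truth recovery,
1000 permutations for the G-score uniformity check, 100–500 for
in-test G-score calls. These sizes are package defaults for testing,
set once; the library APIs accept arbitrary sizes.

## Known limitations

* The permutation null for G scores ignores gene-gene correlation along
  the genome (segments induce runs), so region-level q-values on real
  data are anti-conservative for long events; the thresholded
  class-association path does not share this caveat.
* The moderated t is not a precision-weighted count model; at very low
  counts its calibration degrades (the bundled filter removes most such
  genes).
* Signature forward selection is greedy; strongly collinear catalogs
  can swap closely related signatures (the synthetic catalog is built
  well-separated; COSMIC v2's flat signatures are harder).
* Power/sample-size routines enumerate exactly and are limited to group
  sizes ≤ 200.
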