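# Methods

This note documents the models and procedures implemented in `ribostamp`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic-data generators do and do not emulate.

## Edit calling

### Coordinates and orientation

All coordinates are 0-based half-open internally; SAM and VCF positions
are converted at parse time, BED passes through. Mismatches are recorded
in genomic forward-strand space and re-oriented to the supporting-read
strand only when a conversion is compared with the C>T target: a C-to-U
event on a minus-strand transcript appears genomically as G>A, and the
re-orientation recognises it with a single mechanism that also implements
the antisense filter (below). In 3′ droplet data the read strand tracks
the transcript strand, so read strand is used as the site's orientation;
the strand of a site is the read strand carrying the majority of its
edited reads, ties breaking to `+`.

### Mismatch extraction

Substitutions are reconstructed by walking the CIGAR and MD tags in step:
aligned (`M/=/X`) stretches consume MD match-runs and mismatch letters,
deletions must match `^`-tokens, insertions and soft clips consume query
only, splice skips (`N`) consume reference only and are absent from MD.
The walker validates full MD consumption and raises on any inconsistency;
such reads are counted and skipped, never silently mis-parsed. No
reference FASTA is needed for calling. Bases are excluded when the Phred
quality is below `min_base_qual` (default 20) or the base sits within
`min_dist_from_end` (default 5) bases of either read end, where quality
degrades; both are exposed on the CLI. `N` in read or reference never
counts as mismatch or coverage.

### Read-level exclusions

Unmapped, secondary, supplementary and QC-fail reads are dropped, as are
reads below `min_mapq` (default 0), reads missing the `xf:i:25`
UMI-representative tag when `require_umi_rep_tag` is on (the 10x
short-read convention; default on for short-read mode, off for long-read
and bulk modes where deduplication happens upstream), and reads whose CB
barcode is absent from the whitelist.

### Coverage

Coverage at edited sites is a per-barcode count of passing aligned bases
equal to ref or alt, using the same base-level filters as mismatch
extraction so the two tabulations agree. Reads with a deletion or splice
skip over the position contribute nothing. Per-barcode coverage is
reported for edited barcodes only (a full-pileup mode exists behind a
flag), but the site-level *edited fraction* pools ref/alt over **all**
passing reads at the site: the >5% rule describes the read population at
the locus, and restricting it to edited cells would inflate the fraction
roughly by the inverse of the fraction of cells edited.

### Site-filter cascade

Applied in a fixed order, each site charged to the first rule that
rejects it, with per-rule drop counts returned for auditing:

1. multi-edit-type — more than one distinct alt base at the position;
2. SNP mask — position present in the VCF/BED variant mask;
3. minimum total edits — fewer than 3 edits summed over all cells;
4. maximum edited fraction — more than 5% of pooled reads edited;
5. antisense — supporting-read strand conflicts with every overlapping
   annotated gene (kept if at least one overlapping gene matches);
6. target conversion — after re-orientation, the site must be the
   configured ref→alt (default C→T).

The cascade order is a package choice (the rules themselves are fixed);
placing the cheap set-membership and count checks before the
annotation-dependent ones makes drop counts deterministic and auditable.
Sites overlapping several same-strand genes are counted in each gene when
aggregating to features (rare, documented behaviour).

### Region partitioning

The genome is tiled into half-open intervals; each region tabulates only
observations whose position falls inside it, so every site belongs to
exactly one region, merging is pure concatenation, and a partitioned run
is bit-identical to a single pass (asserted in tests). Memory stays
bounded by region size; time is linear in edited reads.

## Quantification

### EPR

`EPR[c,g] = edits/reads` with both the rate and the edit count zeroed
where reads < 5 (`min_reads`), so downstream sums only see well-covered
pairs. A read may carry several edited positions, so per-gene EPR is not
bounded by 1. Cells are retained when they contain at least 5 edited
genes (short-read rule); the long-read rule excludes cells with 5 or
fewer edited genes — the two stated thresholds differ by the boundary
case and both are implemented literally via `mode=`.

### Mean EPR and Stamp normalization

A cell's mean EPR is the mean of per-gene EPR over *edited* genes (edits
> 0) with at least 3 reads — deliberately 3, not the matrix mask's 5,
following the stated rule; both thresholds are parameters. For cells with
nonzero editor (Stamp) expression, OLS fits
`log1p(mean EPR) = A·log1p(Stamp CPM) + b` (natural log; a closed-form
fit, asserted against an independent least-squares oracle). Residuals are
exponentiated and min–max rescaled onto the [min, max] range of the
uncorrected mean EPR — the rescale formula
`(r' − min r')/(max r' − min r') × (max m − min m) + min m` is the
package's concretisation of "rescaled and shifted to preserve the original
dynamic range". The per-cell factor is corrected/original mean EPR;
zero-Stamp cells and cells with undefined mean EPR keep factor 1. Edits
are multiplied by the factor (fractional counts allowed), re-masked, and
the final EPR is normalized edits over *unadjusted* reads. Degenerate
cases — constant predictor, or a residual spread at float-noise level
(relative width ≤ 1e-12) — yield factor 1 everywhere rather than
stretching noise across the target range.

### Pseudobulk

Per (feature, cell type, sample): pooled `Σedits/Σreads` over that
sample's cells after the per-cell read mask — the pooled ratio, not the
mean of per-cell ratios (a test asserts the difference on an asymmetric
fixture). A feature is retained when, in at least one cell type, **every**
sample has ≥5 total reads, ≥5 total edits, and ≥`min_cells` cells over
the read threshold; `min_cells` defaults to 1 (cell-type analyses) with 5
as the preset used for single-type deep dives — the appropriate value is
context-dependent, so it is a parameter rather than a constant.

### Pseudocells

Within each cell type, cells are shuffled by a seeded generator and cut
into ⌊n/size⌋ chunks; the remainder is dropped to keep pseudocell size
homogeneous (the alternative — a ragged final chunk — would mix
pseudocells of different depth into one matrix). Edits and reads are
summed and EPR recomputed as the pooled ratio; each of the `n_repeats`
shuffles derives its own child seed from the master seed via
`SeedSequence.spawn`, so repeats are independent yet reproducible.

### EditsC

`EditsC[c,t] = edits / (C_t × reads)` where `C_t` counts cytosines on the
mRNA sense strand over the transcript's spliced exons (genomic C on plus
genes, genomic G on minus genes). Transcripts with ≤5 edit-positive cells
are removed. Long-read mode applies only the SNP mask and the target
orientation to per-read edits — the 3-edit/5% site rules are short-read
site-level filters and are not imposed on isoform-aggregated long reads.
Stamp normalization is reusable on the EditsC matrix unchanged.

## States and differential testing

### Translational states

A two-component univariate Gaussian mixture is fitted by EM to the
per-cell total editing rate (`Σedits/Σreads`). Initialization is
deterministic: component means at the 25th/75th percentiles, pooled
variance, equal weights — for 1-D bimodal data this is robust and makes
the fit reproducible without restarts (the `seed` parameter is accepted
for interface parity). Convergence at log-likelihood improvement < 1e-6
or 1000 iterations; variances are floored at 1e-8 of the data variance.
Cells are assigned by maximum posterior and the larger-mean component is
labelled "high". Constant input returns a flagged degenerate fit with all
cells "low". A quantile-band cell filter (e.g. keep cells between the
0.65 and 0.80 quantiles of editor RNA) is provided for state validation
analyses. The fitted parameters agree with scikit-learn's
`GaussianMixture` on shared fixtures (cross-checked in tests).

### Bootstrap differential EPR

Per feature, the pooled per-replicate values of both groups are resampled
with replacement and reassigned to the two groups at their original
sizes; the statistic is the group mean difference, by default in absolute
value (two-sided — the sidedness of the prose definition is ambiguous,
and two-sided matches volcano-style reporting; a one-sided flag exists).
The empirical p is the plain fraction of bootstrap statistics ≥ the
observed one; an optional `(1+k)/(1+B)` smoothing avoids exact zeros.
Resampling is vectorized in feature chunks with independent draws per
feature, fully determined by the seed.

**Known limitation.** With 3 replicates per group this scheme is
intrinsically anticonservative: the empirical distribution of 6 values
underestimates the sampling spread (variance factor 5/6), so null
p-values are not uniform — measured type-I error at p<0.05 is ≈0.055 and
the KS distance from U[0,1] ≈0.10 at 2000 features × 2000 iterations. A
studentized statistic would calibrate, but the implemented statistic is
the raw mean difference by design. Power is unaffected in practice:
planted 10σ shifts are detected at p ≤ 0.05 essentially always.

### Welch test and discordant isoforms

Differential EditsC between cell types uses the two-sample
unequal-variance t-test across samples (scipy; asserted equal to the
closed-form Welch–Satterthwaite statistic to 1e-10). Transcripts with
zero reads and edits in any sample are excluded upstream; the
zero-variance-equal-means corner returns t=0, p=1 instead of NaN.
Discordant genes are those with at least one significant (p < 0.05)
isoform of positive log2FC and one of negative log2FC.

### Stratification and isoform correlations

Quartile labels are rank-based with near-equal bin sizes; ties break by
rank with stable ordering on feature id, so labelling is deterministic.
Extreme-isoform mode keeps transcripts with total reads strictly greater
than 20 across samples and returns each multi-isoform gene's
(argmax, argmin) EditsC pair. Isoform-pair coordination is quantified by
Spearman correlation of the two isoforms' mean pseudobulk profiles across
≥3 cell types, computed identically for EditsC and RNA; constant profiles
are skipped and counted.

## Transcript features

GC content is (G+C)/(A+C+G+T) with N excluded from the denominator and
NaN when nothing remains. Region lengths are spliced interval sums.
Binding-site overlap counts use half-open interval intersection with a
1 bp minimum; each site interval counts once per transcript regardless of
how many of its regions it touches; strand-aware matching is the default
for miRNA/RBP sites (target scans are strand-specific) with a flag to
disable. Inputs must share one genome assembly — coordinate liftover is
out of scope. Group comparisons use the two-sided Mann–Whitney U test,
exact by enumeration when both groups have ≤8 untied observations,
tie-corrected normal approximation otherwise. The 5′TOP scan (terminal C
followed by ≥4 pyrimidines) is labelled a heuristic; curated lists can be
supplied instead.

## Synthetic data

The alignment simulator emulates the *structure* of a 10x-style
experiment: 90 bp single-end reads with CB/xf tags placed uniformly
within single-exon genes on alternating strands, negative-binomial
per-cell-per-gene depth (mean 30, dispersion 10 — deep enough that a
kept site, which needs ≥3 edits at ≤5% fraction and hence ≥60× pooled
coverage, is attainable), per-read Bernoulli C-to-U edits at per-cell-type
rates (defaults 0.02/0.04) on sense-strand cytosines, 5% of reads with a
1 bp insertion and 5% with a 1 bp deletion to exercise the CIGAR/MD
machinery, and planted decoys for every filter rule: multi-alt (3+2 reads
of two alt bases), low-count (exactly 2 edits), high-fraction (≥30% of
covering reads edited), homozygous SNPs (alt in 100% of covering reads,
listed in the VCF), and antisense sites (3 edited among 60 antisense
reads, keeping the fraction under 5% so the strand rule, not the fraction
rule, fires). Decoy edits are planted clear of the read-end exclusion
margin so each decoy falls to its intended rule. Read-level decoys
(non-whitelist barcode, missing xf, secondary, QC-fail, unmapped)
exercise the streaming filters. Long-read mode emits full-transcript
reads with IB isoform tags, two offset isoforms per gene, and per-C
Bernoulli edits, so EditsC truth is exact from per-read edit lists.

The matrix simulator plants `log1p(mean EPR) = A·log1p(Stamp CPM) + b + ε`
with A=0.5, b=0.1, ε~N(0, 0.05) as its default study conditions; library
sizes are fixed at one million so Stamp CPM equals the integer Stamp
count exactly (uniform on 0..12), and per-gene edits are Poisson around
the cell's target rate times the gene's read depth — multiple edits per
read are allowed, which is what makes the planted rates realisable above
1. Differential replicates are Gaussian around a positive base with
shifts expressed in σ units; the EditsC dataset plants discordant,
concordant, single-isoform and null genes with fourfold rate shifts that
dwarf Poisson noise, making exact recovery of the discordant set the
expected outcome under any seed.

What the generators do **not** emulate: sequencing errors, barcode
collisions and correction, UMI structure, doublets/ambient RNA, splice
junctions in short reads, overlapping genes, or empirical distributions
of editing rates. Passing tests therefore demonstrate algorithmic
correctness against planted truth, not robustness to real-data artefacts
— on real data the upstream aligner, barcode correction and the SNP mask
carry that burden.

## Problem sizes

The default test/verification conditions are: ~3,000 simulated short
reads over 2 contigs × 10 kb with 8 genes and 12 cells; ~1,000 long
reads over 4 genes × 2 isoforms and 20 cells; 2,000 cells (5,000 for the
decorrelation check) × 300 genes for normalization; 2,000 features × 3
replicates/group × 2,000 bootstrap iterations for calibration; 1,000–
2,000 cells for mixture recovery. These sizes make every check
deterministic-given-seed and keep a full verification run within a couple
of minutes on one CPU.
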