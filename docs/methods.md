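# Methods

`xenoglia` re-implements, as a tested library, the bespoke computational
procedures used to characterize transcriptional states of human microglia
xenografted into amyloid-pathology mouse brain: droplet quality control and
hashtag demultiplexing, Wilcoxon marker statistics, gene-set module scoring,
cross-dataset cell-state mapping by correlation of differential-expression
signatures with mouse-human ortholog resolution, per-mouse composition
statistics, and a modified Sholl analysis of marker intensity around amyloid
plaques. Every stage is exercised against synthetic data with planted ground
truth; this note records the models, the defaults and why, and what the
synthetic benchmarks do and do not show.

## Synthetic cohorts

Droplet UMI counts follow the standard single-cell negative binomial with
mean/dispersion parameterization, variance `mu + mu^2 / theta`
(`nb_dispersion = 2`, a deliberately noisy setting in the range reported for
variable genes in droplet data). Per-gene baseline means are drawn
log-uniformly over `baseline_mean_range = (0.02, 2)` counts per cell,
giving a realistic detection-rate spectrum without fitting any real dataset.

Each of the eight default cell states (HM, RM, tCRM, CRM-1, CRM-2, IRM,
DAM, HLA) owns a disjoint marker program of `program_size = 20` genes whose
means are multiplied by `2**program_log2_effect` (default effect 1, i.e. a
doubling) in cells of that state. Programs are planted on the top quartile
of baseline expression: marker panels of real microglial states (P2RY12,
CD9, HLA-DRA, CCL3, ...) consist of robustly detected genes, and a 2-fold
shift on a gene seen in a small minority of cells is neither a realistic
marker nor recoverable at the simulated cohort sizes.

Group-level state composition defaults emulate a two-genotype design: a
control group and an amyloid-bearing group in which DAM, HLA and CRM-1
double their share (the remaining states are scaled down to keep the vector
on the simplex). Per-mouse proportions are Dirichlet around the group means
with concentration 150, i.e. a between-mouse coefficient of variation of
roughly 20-25% for a state at 10% abundance — the order of variability seen
between replicate mice — which is what gives the Welch tests real
between-mouse variance to work with.

Droplets are singlets, doublets (rate 0.05) or "negative-like" (rate 0.02,
a cell whose hash staining failed). A doublet is the sum of two
independently drawn parent cells from the same library and carries Poisson
hash signal from both parents; a same-mouse doublet therefore shows signal
on a single hash and is intrinsically invisible to hash-based calling (with
six mice per library this caps doublet recall near 5/6). Hashtag counts are
Poisson with `hash_signal_mean = 200` on the cell's own hash(es) and
`hash_background_mean = 10` elsewhere; the paper-level pipeline gives no
figures for these, so they are free parameters set to a clean but not
trivial 20:1 ratio. A mitochondrial gene block receives a Beta(2, 30) share
of each cell's reads (mean ~6%, occasional cells above the 15% QC cutoff);
the realized per-cell share is recorded in the ground truth, so count
conservation is exact by construction.

What the generator does **not** model: ambient RNA, batch effects between
libraries, empty droplets, depth gradients across samples, or correlated
programs (programs are disjoint by design). Passing recovery benchmarks on
these cohorts therefore demonstrates that the pipeline's statistics behave
as specified under their own assumptions — not that they are robust to the
full messiness of real droplet data.

## Quality control and demultiplexing

Cell filters mirror the standard droplet workflow with strict boundaries as
printed: remove cells with fewer than 1,000 reads OR fewer than 100
detected genes OR more than 15% mitochondrial reads (exactly 1,000 reads or
exactly 15% is kept). A second, per-library stage removes cells whose total
counts or detected genes lie more than 3 sample standard deviations from
the library mean. The outlier rule is applied two-sided by default — the
procedure it reproduces does not state a side — with an `sd_side="upper"`
mode for the reading in which only the high tail (the doublet proxy) is
trimmed. Hard filters run first so that dead cells do not distort library
means; libraries with fewer than three survivors skip the outlier stage.
Stage 1 is idempotent; stage 2 is not in general (removing outliers moves
the mean), which is why the filter reports a removal ledger rather than
being re-applied. Genes detected in fewer than 3 cells are dropped.

Hashtag demultiplexing is a minimal re-specification of classifier-based
hash calling, not a clone of any external function: per hash, log1p counts
across droplets are split by deterministic 1-D 2-means (centers initialized
at min/max), the positivity threshold is the midpoint of the two centers
(fallback: 99th percentile of the lower half when clustering degenerates),
and droplets are classified by their number of positive hashes — none:
negative, one: singlet (assigned to that hash's sample), two or more:
doublet. Validation is against planted truth: across 100 default cohorts,
singlet sample assignment is >99% accurate and doublet recall ~84%
(ceiling ~83-85% given same-mouse doublets).

## Normalization and differential expression

Normalization is log1p counts-per-10k. The upstream study used a
variance-stabilizing regression transform; this package deliberately
substitutes the simpler deterministic transform and records it in the
matrix provenance tag, because all verification here is against synthetic
data generated under known effects, where the substitution changes power
only marginally. Consequences: library-size renormalization compresses
planted fold changes (a planted log2 effect of 1 is measured at ~0.88 when
20 of 600 genes shift together), which the recovery benchmarks absorb.

Marker detection between two cell groups tests only genes detected in at
least 1% of either group AND with mean fold change of at least 0.1 on the
natural-log scale (equivalently |log2FC| >= 0.1/ln 2 ~ 0.144; the stored
column is log2). Fold change uses the field's pseudocount-1 convention,
`log2((mu_a + 1)/(mu_b + 1))` on de-logged normalized means, which bounds
the statistic for zero-mean groups and makes it exactly antisymmetric.
P values come from the Wilcoxon rank-sum test; the Bonferroni multiplier is
the total number of genes in the matrix (the convention of the tooling this
mirrors), with the genes-tested alternative exposed as a flag.

The rank-sum test is implemented in two modes. Exact mode enumerates all
`C(n_a + n_b, n_a)` group assignments (a permutation test on the midrank
statistic, so it remains valid under ties) and is the default for
`n_a + n_b <= 12`, following the convention of standard statistical
software. Normal mode uses midranks, the tie-corrected variance and a
continuity correction. The continuity-corrected normal approximation is
accurate to ~0.016 at n = 6 per group but degrades at very small n (worst
absolute p-error 0.088 at n = 2); this is an intrinsic property of the
approximation, and the automatic exact mode means it is never used at sizes
where it is poor.

## Module scoring

A gene set's score per cell is the mean expression of the set minus the
mean of a pooled control set: genes are placed into `n_bins = 25`
equal-frequency bins of average expression (rank-based binning, robust to
the skew of expression distributions), and each set gene contributes
`n_ctrl = 100` control genes sampled with replacement from its own bin,
seeded. The score is shift-invariant and centred against abundance, so a
positive score means enrichment relative to genes of comparable expression,
not merely high expression. Defaults follow the common convention for
binned-control scoring; the upstream description names none.

## Cross-dataset state mapping

A cluster's signature is its vector of DE log fold changes. Reference
signatures keep genes with p < 0.05 and |logFC| >= 0.25; query signatures
keep p < 0.05 only — the asymmetry mirrors the mapping procedure this
reproduces. Mouse signatures are converted to human identifiers through an
ortholog table with conservative tie-breaking: a mouse gene with several
human orthologs maps to the one with the highest logFC in the human
reference (genes absent from the reference rank lowest); several mouse
genes resolving to one human gene keep the mouse gene with the highest
mouse logFC; unmapped genes are dropped and every decision is written to a
conversion ledger. Ties beyond that break on gene name, so conversion is
deterministic and independent of table row order.

Signatures are compared pairwise by Pearson correlation over shared genes
only (genes present in just one signature are dropped — zero-imputation
manufactures correlation), with at least `min_shared = 10` genes per cell
(the t-transform p on n-2 degrees of freedom is unstable below that);
pairs sharing fewer genes are reported missing rather than zero. Adjusted
p values are Benjamini-Hochberg across all cells of one map (the mapping
being reproduced reports "P-adjusted" without naming the method; Bonferroni
is exposed as a flag), and positive-only masking affects a presentation
column only — r, p and p_adj are always retained.

The overlap statistic between two marker sets is reported in both
directions (percent of A in B, plus Jaccard), since the published "20-25%
overlap" figure does not pin down the denominator.

The risk-gene report counts, for a gene panel matched case-insensitively,
the cells with at least one raw read, and tabulates per-contrast logFC
masked at adjusted p >= 0.05; rows are ordered by average-linkage Euclidean
clustering of the (zero-filled) logFC profile.

## Composition statistics

All between-group tests operate on per-mouse state proportions — the mouse,
not the cell, is the replicate. Two groups are compared with an unpaired
two-tailed Welch t-test (Satterthwaite degrees of freedom, implemented in
closed form and verified against an independent reference to 1e-10); three
or more with one-way ANOVA and Tukey HSD adjusted pairwise p values from
the studentized-range distribution. Proportions are tested untransformed by
default — the upstream wording ("normalized if needed") pins nothing down —
with an arcsine-square-root flag for variance stabilization. Zero-variance
degenerate inputs return the conventional null result (t = 0, p = 1)
rather than NaN.

Embedding density is a per-group Gaussian KDE in which every sample
contributes total weight 1/(samples in group) — per-cell weight
1/(n_samples x n_cells_in_sample) — so density is normalized to sample
size, not cell count. Bandwidth is Scott's rule per group; the evaluation
grid pads the data extent by max(25% of span, 4 bandwidths) so each group's
grid integrates to ~1. Pseudotime distributions use equal-width bins over
the observed range (default 20); per-sample bin proportions sum to 1,
group curves are means of sample curves, and per-bin group differences use
the same Welch test.

## Radial (modified Sholl) profiling

Plaques are segmented in the plaque channel by Otsu or absolute
thresholding, 8-connected components, a minimum-area filter, and sub-pixel
(unweighted centroid) centers. Intensity is then averaged over concentric
annuli around each center: 24 annuli of width 10/3 um covering 0-80 um by
default — the inner three spanning 0-10 um ("near") and the outer three
70-80 um ("distant") — with both the count and the width configurable.
Distances are measured center-of-pixel to plaque **center**, matching the
annulus construction around plaque centers; where neighborhoods of two
plaques overlap, each pixel is assigned to its nearest center only, so no
pixel is double-counted. Annuli extending beyond the image simply contain
fewer (possibly zero) pixels; no padding or reflection is applied.

Channel intensities are z-scored per channel with the sample (n-1)
standard deviation across all (plaque, annulus) means of the table; a
within-image/within-mouse mode is available via the `within` argument.
Curves for display are LOESS (tricube-weighted local polynomials over the
`ceil(span x n)` nearest points, default span 0.75, degree 1) with
pointwise standard errors from the linear-smoother rows and the residual
variance on n - tr(L) degrees of freedom.

The near/far comparison computes, per replicate, the mean of the inner
three and outer three annuli and applies an unpaired one-tailed t-test in
a user-declared direction (markers recruited to plaques: near greater;
homeostatic markers displaced from plaques: far greater). The replicate
unit is a table column: plaque-level by default in the benchmarks,
mouse-level pooling available for designs with few animals. Replicates
missing annuli in either window are dropped with a warning.

Synthetic images plant blurred plaque disks (rejection-sampled centers
with a 25 um minimum separation, so plaques are distinct objects) and
marker channels that decay (`b + A exp(-d/lambda)`) or rise
(`b + A (1 - exp(-d/lambda))`) with distance to the nearest plaque center,
plus Gaussian noise clipped at zero. Benchmarks: the decay length lambda
is recovered within ~5% (tolerance 20%) for lambda in 10-40 um from
noise-free annulus means; with 10 plaques and noise s.d. 10 on amplitude
100, the near/far test is significant in the planted direction in ~100% of
seeds; annulus means are invariant to 90-degree rotation to well under 1%.

## Problem sizes in the benchmarks

The recovery benchmarks run at deliberately modest sizes chosen to give
stable statistics quickly: 100 cohorts of 12 mice x 60 cells for
demultiplexing; 10 cohorts of ~200 cells per state and 600 genes for
marker recovery (pooled recovery fraction ~0.94; single cohorts scatter
0.80-1.00, so the criterion is evaluated on the pooled rate); 100 seeds
each for mapping recovery/null, composition recovery, and the near/far
test; 2,000 draws for Welch type-I calibration. The full acceptance run
completes in about a minute on one CPU.

## Known limitations

- The log1p CP10K stand-in means absolute logFC values are not directly
  comparable to pipelines using regression-based transforms on real data.
- The 3-s.d. outlier rule's sidedness and the exact multiple-testing
  method behind the mapping's "P-adjusted" are ambiguous upstream; both
  choices here are defaults with the alternative exposed.
- Hash demultiplexing is threshold-based per hash; it does not model
  per-droplet background (as latent-variable demultiplexers do) and is not
  expected to match any specific external implementation call-for-call.
- The radial analysis is strictly 2-D and ignores plaque size when
  measuring distance (center, not edge, by design).
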