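# Methods

This note documents the models, parameter choices and numerical conventions
behind `scrobust`, and what the synthetic cohorts do and do not establish
about behavior on real data.

## Quality control and normalization

Three rules are evaluated **against the unfiltered input matrix** in a
single pass, so their per-rule counts are unambiguous and order-independent:
(i) detected genes < `min_genes` (default 500); (ii) detected genes or total
UMIs strictly above the `doublet_quantile` (default 0.98) sample quantile —
linear-interpolation quantile, strict inequality, so a fully tied input
removes nothing; (iii) mitochondrial read fraction strictly above `mito_max`
(default 0.10), over genes flagged by the `mt-`/`MT-` symbol prefix or an
explicit 13-gene list. When no gene is flagged mitochondrial the rule is
skipped and recorded as a warning in the QC report.

Normalization is `ln(1 + 10⁴·raw/LS)` with the natural log and pseudo-count
1 exactly; no base-2 variant is offered. Cells with zero library size must
be filtered first (error otherwise).

## Confound scoring and regression

Signature activation is the mean normalized expression of the signature
genes minus the mean over a background multiset: for each signature gene,
its 10 nearest non-signature genes by Euclidean distance in z-standardized
(mean, variance) space. The multiset convention (a control gene backing two
signature genes counts twice) is the default; a deduplicated union is
available. Because backgrounds are matched on expression and variance, a
random signature scores ≈0 in every cell regardless of coverage.

Confound removal fits `x_gj = a_g + b_g·s_j` per gene and returns
`x_gj − b_g·(s_j − mean(s))`: the least-squares residual plus the gene's
mean. This leaves every gene exactly uncorrelated with the score (residual
orthogonality), preserves per-gene means so log-space location stays
interpretable, and is idempotent. The raw (unstandardized) score is used;
a constant score degenerates the fit and returns the input with a warning.
The derived confound signature takes clusters whose stained-label fraction
is ≥ 0.9 ("heavily dominated"; the threshold is this package's default) and
returns genes overexpressed in them (FC > 1.25, Q < 0.1).

## Variable genes and components

Dispersion is variance/mean of normalized values. Genes are placed in 20
equal-frequency bins of mean expression (the r-th smallest mean goes to bin
⌊r·q/m⌋ — an explicit convention so an independent reimplementation agrees
bit-for-bit), and genes more than 1 SD above their bin's mean dispersion
are selected. Genes are centered but not variance-scaled before PCA
(scaling would erase the dispersion signal); components get a deterministic
sign (largest-magnitude loading positive).

The component-selection permutation test permutes each gene independently
across cells, re-runs PCA, and keeps the prefix of components whose
explained variance exceeds the rank-matched (1 − α) null quantile
(α = 0.05, 100 permutations standalone). The statistic is per-rank explained
variance; the choice is recorded in config so it can be swapped.

**Clustering basis.** The graph-clustering stage uses the fixed top
`n_components` (default 20) PC basis rather than the permutation-selected
prefix. On low-rank planted data the permutation test correctly keeps only
the structure components, but community detection in a 2–3-dimensional
space over-partitions: KNN graphs of even isotropic point clouds in few
dimensions are themselves modular, so Louvain splits genuine populations
into geometric fragments. Retaining the full top-20 basis leaves planted
populations intact (the trailing noise components de-modularize the
within-population graph) and makes the shuffled null behave sensibly. The
permutation-selected basis remains available
(`ReductionParams.pc_selection="permutation"`); when the permutation test
selects nothing, the full computed basis is kept — no evidence for a
truncation means no truncation.

t-SNE (Barnes-Hut, perplexity 30, 10,000 iterations, seeded) is invoked
from scikit-learn for visualization only; nothing downstream consumes the
embedding.

## Resolution selection

The KNN graph uses exact Euclidean k-nearest neighbors on the PC basis;
the neighbor set of a node includes the node itself, and edge weights are
the Jaccard overlap of the two endpoint sets (zero-weight edges dropped).
Louvain (igraph multilevel, seeded RNG, deterministic node order) maximizes
weighted Newman–Girvan modularity; the reported modularity is verified
against a brute-force computation in the tests. Leiden is available as a
configurable alternative and is recorded in provenance when used.

The null for resolution selection permutes each cell's values across genes,
preserving the cell's value multiset (hence coverage biases) while
destroying gene identity. For each k, S_k is the **mean** modularity over
`n_shuffles` (default 100) shuffled matrices, with HVG selection and PCA
recomputed per shuffle; the observed O_k comes from the same sub-pipeline.
The chosen resolution is the k with the most clusters among those with
O_k/S_k ≥ 2 (ties: higher modularity, then smaller k); if none qualifies
the scan returns "none", which on within-cell-shuffled inputs is the
expected outcome. Inside the scan the optional permutation PC selection
uses 25 permutations per shuffle (configurable) to keep a 100-shuffle scan
desk-scale; the standalone selector default stays 100.

The contaminant purge removes (1) whole clusters whose B-cell marker
detection rate (any of Cd79a/Cd79b by default) is ≥ 0.5, and (2) individual
cells above the 0.99 quantile of |score| on components whose top-decile
absolute loadings contain a marker gene. The purge returns a mask; the
pipeline re-runs the entire processing on retained cells, at most twice.

## Differential expression

The moderated t-test is a two-group empirical-Bayes design: per-gene pooled
variances s² (df d = n₁+n₂−2) shrink toward a prior s₀² with prior df d₀,
via the posterior (d₀s₀² + d·s²)/(d₀+d) and a t reference with d+d₀ df.
The prior is moment-matched through the scaled-F marginal s² ~ s₀²·F(d, d₀):
closed-form d₀ and s₀² from the mean and squared CV of the positive sample
variances, with d₀ = ∞ (complete shrinkage) when variances are
underdispersed relative to any finite prior. At d₀ = 0 the statistic is the
ordinary pooled t, which coincides exactly with Welch's t when group sizes
and sample variances agree — the cross-check mode used in the tests. Genes
with zero variance in both groups get p = 1 by convention. BH correction is
applied per contrast.

Fold change is the linear-space ratio of group means of normalized values
with an ε = 1e-9 floor on both means. Cluster-defining genes must pass
FC > 1.25 and Q < 0.1 — both strict, both replicates independently.
Subpopulation signatures additionally require a detection-rate difference
> 0.1 in both replicates (the margin is this package's default; detection
is the fraction of cells with ≥ 1 raw read). The three-way cross-dataset
characterization calls a gene A-specific when it passes A-vs-rest-of-X and
A-vs-B; replicate-joint interpretation is done by running the procedure per
replicate and intersecting. The external-signature overlap test is an
upper-tail hypergeometric. The cross-cohort comparison computes per-lesion
detection rates of a signature and applies a two-sided Wilcoxon rank-sum
test across lesions (the lesion, not the cell, is the unit of analysis),
BH-adjusted across signature genes.

## Cluster matching and meta-clustering

Fingerprints are per-cluster fold-change vectors against the pooled rest of
the same dataset (ε = 1e-9, capped at 10⁴), so any multiplicative
per-dataset per-gene factor cancels. Pearson correlation is computed on
**log** FC (ratios are multiplicative; a handful of extreme genes would
otherwise dominate), with a raw-FC mode behind a flag for fidelity checks.

The correlation universe is the intersection of the datasets' genes
restricted to genes detected in ≥ 5% of some cluster's cells on each side
(`matching.MIN_DETECTION`; 0 restores the plain intersection). Essentially
undetected genes have near-zero group means, so their ε-floored fold
changes are numerical noise; on simulated replicate pairs they reduced
true-pair correlations from ≈0.6 to ≈0.2 and erased the matching signal.
An HVG-union universe was evaluated and performed worse under strong batch
effects.

Robust calling: per dataset, threshold = mean + 1.2816·SD over all its
cross-replicate correlations (the 4-decimal upper-tail normal quantile at
p = 0.1); a cluster is robust iff its best match strictly exceeds the
threshold, so a zero-SD correlation matrix yields no robust clusters.
Meta-clustering is agglomerative (average linkage by default; complete
available) on 1 − r, cut by requested count or height; curated merges are
explicit config directives recorded on the result. The Euclidean baseline
runs the same agglomeration on distances between raw mean-expression
vectors — on batch-affected simulations it groups clusters by dataset while
the FC-correlation tree groups them by planted program, which is the
method's motivating contrast.

## Synthetic cohorts

The generator emulates a multi-tissue, two-replicate study: per-cell
program labels over `n_programs` planted programs; gamma(0.7) baseline
expression (a realistic mean–dispersion trend for the binned HVG selector);
per-dataset per-gene lognormal batch factors (`batch_sd`); lognormal
library sizes (median 4,000 UMIs, log-SD 0.3 by default, chosen so a
1,000-gene universe yields a median of ~740 detected genes and the
500-detected-genes filter trims only a small-library tail, as in real
data); Poisson counts conditional on the rate, with optional gene-level
overdispersion (negative binomial); doublets formed **before** normalization
by summing two same-dataset singlets (guaranteeing high UMI and gene counts
for the quantile rule); 13 `mt-` genes carrying ~4% of baseline expression,
with high-mito cells reallocating 25% of their UMIs into them while
preserving library size; CD79⁺ contaminants with near-silent marker
baseline in normal cells (detection < 1%) and forced marker detection in
contaminants; and an activation-like confound that adds
Poisson((e^effect − 1)·raw) counts on signature genes in a uniformly chosen
cell subset, exactly a no-op at effect 0.

Program effects default to e-fold 3 on 3% of genes per program, disjoint
across programs. Defaults are the study conditions for the acceptance
simulations; tests that probe detection-rate behavior use smaller libraries
(~800 UMIs) so detection is informative rather than saturated.

**What the synthetic cohorts do not model**: gene–gene correlation within a
program beyond the shared mean shift, ambient RNA, UMI collisions,
cell-cycle structure, continuous (trajectory-like) state gradients, and
empty droplets. Passing recovery tests therefore demonstrates the
pipeline's logic and calibration under its own assumptions, not performance
on arbitrary real data.

## Problem sizes and determinism

The acceptance computations use 2,000-cell × 1,000-gene cohorts with 20
shuffles for the resolution scan, and 3 tissues × 2 replicates × 600 cells
for the matching head-to-head; both finish in well under a minute on one
CPU. Every random stage derives its seed deterministically from a master
seed and the stage name (SHA-256, < 2³¹), so identical configs reproduce
byte-identical outputs; the pipeline writes a stage manifest of input
hashes and skips completed per-dataset stages on resume.

## Known limitations

- The resolution scan's null recomputes HVG/PCA per shuffle but reuses the
  same gene universe; whether the original analysis reused the observed PCA
  basis is not recoverable, so both modes exist behind a flag.
- Robust calling pools all cross-replicate correlations of a dataset for
  its mean/SD; pooling best matches only is a flagged alternative.
- The moderated t-test implements the plain two-group contrast (no trend or
  robust variants).
- Ortholog translation requires a user-supplied two-column table; no live
  lookup is performed, and unmapped symbols are returned, never dropped.
- Meta-cluster count/height is a required analysis choice, not estimated
  from data; curated merges must be given explicitly and are logged.
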