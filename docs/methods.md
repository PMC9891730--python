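# Methods

`frusc` re-implements, as a reusable library, the computational workflow
used to build single-cell atlases of sexually dimorphic *Drosophila*
neurons — quality control, normalization, principal-component selection,
graph clustering, marker-gene detection, sex-bias classification,
rule-based annotation, co-expression summaries, downsampling robustness,
and targeted subclustering — together with the locomotor-activity
analysis (sleep and circadian period) used for functional follow-up.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data generator does and
does not emulate.

## Count model and quality control

Input is a genes × cells UMI matrix (10x-style Matrix Market triplet plus
a cell-metadata TSV with sex and replicate). In memory the pipeline uses
`AnnData` in the scanpy convention (cells × genes).

Per-cell QC metrics are the number of detected genes (UMIs > 0), total
UMIs, and the mitochondrial UMI fraction (genes identified by a
configurable id prefix, default `mt:`, following fly nomenclature; the
fraction is defined as 0 for an all-zero cell). The default filters
remove cells with

- mitochondrial fraction > 0.05 (stressed/dying cells),
- fewer than 200 detected genes (empty droplets),
- more than 4000 detected genes, or
- more than 20,000 UMIs (multiplets).

All four comparisons are strict, so a cell sitting exactly on a boundary
is kept. Filtering is idempotent and partitions the input exactly into
kept and removed cells. Cells are classified as neurons when any of
*elav*, *nSyb*, or *noe* is detected; "detected" throughout the package
means raw UMIs > 0.

## Normalization, variable genes, PCA

Counts are library-size normalized and log-transformed:
`x = ln(1 + count / cell_total × 10⁴)`. Zeros map to zeros and a
zero-total cell becomes a zero vector (with a warning). Highly variable
genes are ranked by mean-binned standardized dispersion of the
log-normalized data (scanpy's Seurat flavor), deterministically with ties
broken by gene id; the top 2000 are used by default. Before PCA, genes
are centered, scaled to unit variance, and clipped at ±10.

### Jackstraw PC selection

The number of informative PCs is chosen by a permutation ("jackstraw")
test. In each of `n_reps = 100` replicates, a random `prop = 5%` of the
variable genes is permuted across cells and PCA is re-run; the absolute
loadings of the permuted genes pool into a per-PC null. Every observed
gene receives an empirical p-value per PC, and the per-PC p-value is a
one-sided binomial test of how many genes fall below a gene-level
threshold of 1e-3. The selected count is the run of significant PCs
(p < 0.05) up to the first non-significant one.

The extreme gene-level threshold matters. Because every observed gene
both defines the PCs and is scored against genes excluded from defining
them, moderate gene-level p-values are slightly inflated even on pure
noise (≈6% fall below 0.05 instead of 5%); a proportion test at a
moderate threshold therefore calls noise PCs significant far more often
than its nominal level, while the far tail of the null stays calibrated.
With the 1e-3 threshold, simulations with pure-noise matrices select
zero PCs in ≈100% of seeds while power on planted cluster structure is
unchanged. When a caller supplies too small a permutation null to
resolve the threshold, it is widened to `2/(null size + 1)` with a
warning. Selecting zero PCs raises an error unless `min_pcs` forces a
minimum; `min_pcs` also acts as a floor because graph clustering on a
one-dimensional embedding degenerates (a k-NN chain is segmented rather
than split at density gaps).

## Clustering

A k-nearest-neighbor graph (`k = 20`, self-inclusive) is built on the
retained PC scores and re-weighted by the Jaccard overlap of
neighborhoods; edges below 1/15 are pruned (the conventions of the
Seurat SNN graph). Communities are found by modularity optimization at a
caller-chosen resolution — Louvain (igraph's multilevel algorithm) by
default, Leiden optionally — with a mandatory seed. Labels are
relabeled contiguously by decreasing cluster size. UMAP (via
`umap-learn`) provides a seeded 2-D embedding for visualization only;
no downstream statistic depends on it.

Resolution is a free parameter, as it is in the tools this mirrors: the
reference atlas chose per-dataset resolutions by inspection (3.0 for its
full data set at n ≈ 25,000 cells). On the synthetic scale used in this
package's tests (a few hundred cells, 3–5 planted clusters), resolutions
near 0.3–0.5 recover planted partitions with ARI ≥ 0.9; higher values
begin to split large clusters, which is expected modularity behavior,
not a failure mode.

## Marker genes and sex-differential expression

For each cluster, candidate genes must be detected in ≥ 25% of cells of
the cluster or of the rest (`min_pct`, either-group semantics), and must
have a natural-log fold change ≥ 0.25, computed on de-logged means with
a pseudocount: `ln((mean(expm1 x)_in + 1) / (mean(expm1 x)_out + 1))`.
Surviving genes are tested two-sided with the Wilcoxon rank-sum test on
log-normalized values: exact when both groups have ≤ 8 tie-free values,
otherwise the normal approximation with mid-rank tie correction and no
continuity correction. Only positively enriched genes are reported.
Bonferroni correction multiplies by the total number of genes in the
matrix; both raw and adjusted p-values are reported and the significance
filter column is configurable (raw by default). Within-cluster
sex-differential expression applies the same machinery to male vs female
cells inside each cluster (both directions; clusters lacking three cells
of either sex are skipped with a recorded reason).

## Sex-bias classification

Let `s` be the ratio of total female to total male cells in the filtered
matrix (the reference atlas's value is 17,530 / 7,988 ≈ 2.19). Per
cluster, the female count is divided by `s`; a cluster is *sex-specific*
if the other sex contributes zero **raw** cells, *strongly sex-biased*
if the larger-to-smaller ratio of male vs normalized female counts
exceeds 4, *sex-biased* if it exceeds 2, else unbiased — strict
inequalities, specificity taking precedence, ratio reported as infinity
for specific clusters. The classification is sex-symmetric (swapping
sexes and inverting `s` mirrors every class) and monotone in either
count. Sex-DE genes aggregate into uniquely-male / uniquely-female /
mixed sets across clusters.

## Annotation rules

Cluster labels come from a declarative rule set over marker-gene
membership (vocabulary configurable as JSON):

- **VNC**: any Hox marker (*Antp*, *Ubx*, *abd-A*, *Abd-B*).
- **αβ Kenyon cells** (high confidence): ≥ 1 of {*ey*, *Dop1R2*} and
  ≥ 1 of {*sNPF*, *Fas2*} as markers, *trio* absent; **γ KC** when
  *trio* is additionally a marker (the two are mutually exclusive).
- **KC, low confidence**: both *sNPF* and *Fas2* markers with a core
  gene expressed in ≥ 25% of the cluster but not a marker, or *trio*
  plus exactly one of {*Fas2*, *Dop1R2*}. The 25% detection cutoff for
  "expressed but not a marker" is this package's assumption (chosen to
  match `min_pct`); the original criterion states no number.
- **Fast-acting neurotransmitters**: cholinergic (*VAChT*/*ChAT*),
  GABAergic (*Gad1*/*VGAT*), glutamatergic (*VGlut*); multi-label
  allowed.
- **Aminergic**: *Vmat*; dopaminergic (*DAT*/*ple*), serotonergic
  (*SerT*), tyraminergic/octopaminergic (*Tdc2*).
- **Circadian**: at least two of {*per*, *tim*, *Clk*, *vri*, *Pdp1*}.
- Optional neuropeptide/receptor flags from user-supplied lists.

The engine is pure (same inputs → same labels; unrelated clusters cannot
affect each other) and is verified in tests against an independently
written naive re-evaluation of the rules on randomized marker tables.
Cell-level classifiers (gene-set flags, SerT ∧ (abd-A ∨ Abd-B)
selection, aminergic × FAN co-transmission proportions) use raw UMIs > 0
membership.

## Co-expression

Pairwise gene correlations (Pearson default, Spearman optional) are
computed on log-normalized values over all cells or a caller-supplied
subset; constant genes yield missing values rather than zeros. Euler-style
exclusive overlap fractions for a gene trio partition the cells
expressing at least one member.

## Downsampling robustness and cluster matching

Downsampling removes whole cells uniformly at random per sex (never
thinning counts) to a target count, seed-reproducibly. Re-analyzed
clusterings are matched back to a reference by Spearman correlation of
per-cluster mean log-normalized profiles over the reference's variable
genes; a query cluster is assigned to its argmax-correlation reference
cluster when ρ ≥ 0.5, else left unassigned. A concordance report flags
reference clusters whose sex-bias class changes or goes unmatched across
runs. A separate mode recounts composition under the original labels
without re-clustering.

## Subclustering

A subcluster specification selects cells by source-cluster membership
and conjunctive gene predicates (e.g. *dsx* UMIs > 0), reuses the
parent's normalization, re-selects variable genes on the subset, re-runs
PCA (fixed PC count or jackstraw re-selection), clusters, and recomputes
markers and per-subcluster sex composition. Three stock configurations
mirror the reference atlas's focused re-analyses: *dsx* (clusters
{21, 47, 68}, dsx > 0, 27 PCs, resolution 0.5), Kenyon cells (21 PCs,
resolution 0.5), circadian (2 PCs, resolution 2.5); the fixed PC counts
are properties of that data set, so jackstraw re-selection is the
default on other data.

## Activity analysis

Traces are per-fly 1-minute beam-cross counts (length a multiple of
1440) with a light schedule. Flies with any full day under 50 counts are
removed as dead (strict inequality). Sleep bouts are maximal runs of
≥ 5 consecutive zero minutes — equivalent, for total sleep time, to the
5-minute sliding-window convention — split day/night at the schedule
boundaries.

The circadian period is estimated with the Sokolove–Bushell chi-square
periodogram on a grid from 18 to 30 h in 0.2 h steps. For each candidate
period `P` minutes the trace folds into `P` one-minute bins over `K`
complete cycles (partial final cycle dropped) and

    Qp = K · Σ_h (M_h − M)² / s²,

with `M_h` the bin means, `M` the grand mean, `s²` the variance of the
folded samples; under the null Qp ~ χ²(P − 1). A fly is rhythmic when
max Qp / Qp_crit ≥ 1 and its period is the grid point maximizing Qp
among significant ones. Because 61 periods are tested, the critical
value uses a Bonferroni-corrected alpha by default — with the raw
per-period threshold an arrhythmic fly crosses the line somewhere on the
grid almost surely, and the package's own null simulations demand a
calibrated test; `correct="none"` restores the per-period line. Group
summaries exclude arrhythmic flies from period statistics and report the
exclusion count.

## Synthetic data

`simulate_counts` draws negative-binomial UMIs (gamma–Poisson, variance
`m + φm²`, dispersion φ = 0.5 by default) for a configurable
cluster × sex cell table (default 5 clusters × 50 cells per sex, 1000
genes, baseline mean 0.5 UMIs/gene). Non-marker genes receive lognormal
per-gene baseline means (log-scale sigma 1.0) so variable-gene selection
faces a realistic mean–dispersion landscape; each cluster gets 40
disjoint marker genes whose means are multiplied by `marker_fold`
(default 4) inside the cluster. Marker and mitochondrial genes sit at
the typical mean so the planted fold is exact and healthy-cell
mitochondrial fractions stay tightly near 1%. Artifacts (2% each by
default): empty droplets (means rescaled by solving for ≈100 expected
detected genes), high-mito cells (mitochondrial means inflated to an
expected 30% fraction), multiplets (sums of two random clean cells).
Zeros in the cell table plant sex-specific clusters. The 40
markers-per-cluster default reflects the scale reported for real
atlases of this kind (tens to hundreds of enriched genes per cluster).

`simulate_activity` emits Poisson counts at rate
`baseline · (1 + amplitude · w(t))` with `w` a sinusoid or square wave
at the planted period, optional nightly zero blocks for consolidated
sleep, and a leading block of "dead" flies emitting ≈0 counts.

What the generator does **not** emulate: ambient RNA, batch/chemistry
effects needing integration, gene–gene correlation beyond cluster
structure, realistic gene-length or GC biases, depth variation between
cells beyond NB noise, and doublets between specific cell types.
Passing recovery tests therefore demonstrates the pipeline's
correctness on data satisfying its own model assumptions, not
performance on real tissue.

## Problem sizes and determinism

Tests and the acceptance script run at deliberately small scale (a few
hundred cells, ≤ 1000 genes, 10-day activity traces, ≤ 100 Monte-Carlo
seeds per property), which keeps every planted effect detectable while
the whole suite completes in about a minute. Every stochastic stage
takes an explicit seed; identical inputs and seeds reproduce outputs
bit-for-bit (the pipeline's run manifest records all parameters and
versions).

## Known limitations

- The Seurat-flavor HVG ranking differs across tool versions; the method
  used is recorded but no attempt is made to match any specific
  version's gene list.
- Louvain community detection depends on igraph's RNG; determinism holds
  for a fixed igraph version and seed.
- The jackstraw's gene-level threshold (1e-3) trades a small amount of
  sensitivity to very weak PCs for calibrated type-I behavior; extremely
  subtle structure may require more replicates and a larger permutation
  proportion.
- The rank-sum normal approximation (used whenever a group exceeds 8
  values or ties exist) is the standard large-sample path; exact
  p-values for large tied samples are out of scope.
- Periodogram binning rounds candidate periods to whole minutes, which
  is exact for the default 0.2 h grid.
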