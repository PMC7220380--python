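# Methods

## Scope and model of the data

mesentrace analyzes UMI count matrices (genes × cells) from a tissue whose
cells lie on a Y-shaped differentiation topology: a progenitor pool at the
root, a shared trunk of intermediate states, one branch point, and two
terminally differentiated fates. The motivating system is endosteal
bone-marrow mesenchyme — early mesenchymal progenitors differentiating
through intermediate and lineage-committed states into osteoblasts/
osteocytes on one branch and marrow adipocytes on the other — but every
stage is written against the abstract topology, not the tissue.

Counts are treated as negative binomial: `Var = μ + φμ²` with per-gene
dispersion φ. All stages that need a parametric count model (dispersion
estimation, the branch LRT, lineage trends) use this family; everything
rank-based (markers, the permutation test) does not.

## Quality control and normalization

A cell is excluded iff it detects more than `max_genes` (default 6,000)
or fewer than `min_genes` (default 200) genes, or more than `max_pct_mito`
(default 5) percent of its UMIs map to mitochondrial genes, identified by
the `mt-` name prefix. The predicate is strict, so cells exactly at a
boundary are retained; the mitochondrial fraction is computed on UMIs, the
usual convention. The gene-count ceiling doubles as a crude doublet
filter.

Normalization scales each cell to `scale_total` (default 10⁴) molecules
and applies ln(1+x); it is exactly invariant to per-cell scalar scaling of
the counts. Covariate regression fits, per gene, an OLS model on intercept
+ total UMIs + mitochondrial percentage and keeps the residuals; constant
or collinear covariate columns are dropped with a warning (earliest column
of a dependent group wins). Residuals are exactly orthogonal to the
retained design columns; they may be negative, so dispersion estimation
uses the pre-residual counts, and the residualized matrix feeds only PCA.

## Dispersion and gene selection

Empirical dispersion is the NB method-of-moments estimate
`φ̂ = max(0, (s² − m̄)/m̄²)` on counts scaled per cell to the median library
size. Degenerate genes (zero mean or variance ≤ mean) get φ̂ = 0. The
mean–dispersion trend `φ(μ) = a + b/μ` is fitted by a gamma-family GLM
with identity link over genes with positive mean and dispersion (least
squares fallback if the GLM fails); fitted values are floored at 10⁻⁸ so
ratios stay defined.

Two selectors sit on top: the ordering-gene rule
(`mean ≥ 0.05` and `φ̂ ≥ 2·φ(μ)`, both inclusive) used for trajectory-
related testing, and top-k by the ratio `φ̂/φ(μ)` (default k = 2,000, ties
broken by gene id) for PCA/clustering. Ranking by the ratio rather than
raw dispersion avoids selecting genes merely for being highly expressed;
both knobs are exposed because the two selections serve different stages.

## Clustering

PCA (default 30 components) runs on centered, unit-scaled residual
expression of the highly-variable genes; zero-variance genes are centered
only. The SNN graph includes each cell in its own neighborhood
(k = 20 + self), weights edges by neighborhood Jaccard similarity, and
prunes weights below 1/15. Community detection is Leiden
(RBConfiguration, resolution 1.0, fixed seed, run to convergence) via
python-igraph/leidenalg — this stage is a standard-library computation,
not a contribution of this package. Markers use a two-sided Wilcoxon
rank-sum test (asymptotic, ties handled; constant genes forced to p = 1),
AUC = U/(n₁n₂), log fold-change ln((m₁+1)/(m₂+1)) of depth-scaled means,
and BH correction across genes.

tSNE/UMAP embeddings are provided for plotting only; no downstream stage
consumes them by default. The trajectory runs in PC space because 2-D
embeddings distort long-range distances, though any coordinate matrix can
be passed in.

## The proliferative-cell permutation test

Inputs are disjoint S-phase and G2/M gene lists (shipped as user files;
the classic core set has 43 + 54 genes). Genes absent from the matrix or
expressed in fewer than 5% of cells are dropped first; with typical
sparsity this leaves a few dozen genes per set.

Per cell, the observed statistic is the difference in mean log-normalized
expression between the S set (size n_S) and the G2/M set (size n_G). The
null distribution is built by relabeling: draw n_S of the pooled
n_S + n_G genes as pseudo-S (sampling without replacement) and recompute
the difference. One set of B = 5,000 resample index sets is drawn per run
and shared by all cells — statistically equivalent to independent streams
and exactly reproducible. The two-sided Monte-Carlo p-value is the
add-one estimator `(1 + #{|d*| ≥ |d|})/(B + 1)`, which is valid (never
anti-conservative) under sampling; when C(n_S+n_G, n_S) ≤ 10⁵ the
implementation enumerates every split instead and reports the exact
`#{|d*| ≥ |d|}/C`, valid because the observed split is itself among those
enumerated. Ties with the observed statistic count as extreme (absolute
comparison with a 10⁻¹² tolerance). Note the null of the mean difference
is asymmetric when n_S ≠ n_G, so the absolute-value count is not exactly
twice a tail probability; it is the estimator used consistently in both
modes, which is what the oracle-equivalence test checks.

BH correction is applied separately within each cluster, mirroring the
idea that each population is its own family of tests; a cell is
proliferative iff its within-cluster FDR < α (default 0.05), and its
dominant set is S or G2/M by the sign of the observed difference. Two
consequences are inherited deliberately: a cell with both modules equally
elevated is non-proliferative (the statistic is a difference), and
per-cluster correction means a cell's call can change if the clustering
changes.

## Trajectory

Cluster centroids in the reduced space are joined by a Euclidean minimum
spanning tree (Kruskal; edges sorted by (length, smaller id, larger id)
so ties are deterministic). Rooting at a designated progenitor cluster
makes each root-to-leaf path a lineage; nodes of degree ≥ 3 on those
paths are branch points. Cells project orthogonally onto the nearest
segment of a lineage path containing their cluster (clamped to segment
ends; ties by smaller arc length), and pseudotime is arc length from the
root start. Cells in clusters shared by all lineages are labeled
`trunk`; cells past the branch point get their lineage id. Pseudotime is
invariant to rigid motions of the reduced space.

This is a deliberate simplification of curve-based trajectory methods:
no simultaneous principal curves, no nonlinear tree embedding. The
simplification keeps every step specifiable and testable while producing
the same qualitative object — a rooted Y with the progenitor population
at the origin. Root selection is user-specified in the library API; the
end-to-end pipeline, when no root is given, picks the MST leaf whose
cluster has the highest proliferative fraction (progenitor pools cycle,
terminal fates do not) so a default run completes unattended.

## Branch-dependent expression

For cells past the branch point, each gene's counts are modeled by an NB
log-link GLM with log library-size offset. The full model gives each
branch its own intercept and natural cubic spline in pseudotime (df = 3,
boundary knots at the pseudotime range, interior knots at quantiles); the
reduced model shares one spline. The likelihood ratio is referred to
χ²(4) — one branch intercept plus three branch-specific spline contrasts
— with BH correction across genes. Per-gene dispersion is the
method-of-moments estimate held fixed during fitting; profiling it per
model would be slower and less robust at these sample sizes, and the LRT
compares two models sharing the same φ. Genes whose NB fit fails fall
back to a Gaussian LRT on log-normalized expression (logged); all-zero
genes are reported flat with p = 1 and no fit.

Lineage trends regress counts on pseudotime (linear term, same offset);
direction is the slope's sign when the BH-adjusted Wald p falls below the
threshold, else flat. The branched heatmap bins cells per branch along
pseudotime (default 20 bins), smooths rows with a rolling mean confined
to each branch block, orders columns terminus → branch point → terminus,
and groups genes by the branch in which the smoothed profile peaks, with
gene-id tie-breaks so the ordering is independent of input order.

## Synthetic data generator

The generator is the package's test bed: it plants exactly the structure
the analysis assumes and returns full ground truth. Defaults define the
study conditions: six populations (EMP, LMP, LCP on the trunk; OB, Ocy
osteogenic; AD adipogenic) × 500 cells; 2,000 genes of which 25 per
population are markers (log-fold 2.0), 40 per branch ramp linearly in
log-space from the branch point to a 2-fold terminus divergence, 43 S and
54 G2/M cycle genes, 1% mitochondrial genes, and the rest background with
log-normal baseline expression; library sizes log-normal
(median ≈ 5,000 UMIs, σ = 0.35); NB dispersion 0.2, in the range typical
of UMI data. Each population occupies a unit pseudotime interval and a
cell's log-mean interpolates linearly between the anchor profiles at
flanking population centers (trunk cells past the fork center head toward
the average of the two branch-head profiles), so expression varies
continuously along each path — the property that makes centroid MSTs
recover the planted Y. Cycling fractions default to EMP 0.20, LMP 0.15,
LCP 0.10, OB 0.05, Ocy/AD 0 — cycling confined to progenitors, as in
marrow — and each cycling cell has exactly one cycle module (S or G2/M,
50/50) up-shifted by δ = 1.0 in log space. Counts are gamma–Poisson draws
around the library-scaled program means; identical parameters and seed
give byte-identical fixtures.

What the generator does not emulate: doublets, ambient RNA, batch
effects, gene–gene correlation beyond the shared programs, and
zero-inflation beyond what NB sampling produces. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to those artifacts.

## Numerical choices and degenerate inputs

Ties: gene-id lexicographic order in top-k selection and heatmap
ordering; (length, id-pair) in MST edges; earliest-column-wins when
dropping collinear covariates. Floors: 10⁻⁸ on fitted dispersion and on
the MoM dispersion used in GLMs; 10⁻¹² tolerance on permutation tie
comparisons. Zero-total cells are a hard error after QC (they cannot be
log-normalized); all-zero genes propagate as zero rows, zero dispersion,
flat trends. Exhaustive permutation mode refuses enumerations beyond 10⁵
splits rather than attempting them.

## Validation problem sizes

The test suite validates each stage against independent oracles at sizes
chosen to make the checks sharp but quick: exhaustive split enumeration
for 5–12 cycle genes (50 random cells plus a 5-gene hand-worked toy);
2,000 null cells × 20 seeds for type-I error of the proliferation calls;
the 3,000-cell default fixture for power (sensitivity ≥ 0.9 at δ = 1.0),
clustering ARI (≥ 0.8), and lineage/pseudotime recovery (exactly two
lineages at the planted termini, Spearman |ρ| ≥ 0.8); brute-force
spanning-tree enumeration via Prüfer sequences for ≤ 5 clusters; planted
high-dispersion genes (precision/recall ≥ 0.9); and 450 null genes across
3 seeds for branch-test calibration. The NB consistency of the generator
is checked by a variance-ratio test on the default fixture rather than a
formal per-gene goodness-of-fit: per-cell means vary along the lineage,
so a single-(μ, φ) GOF would be misspecified by construction.

## Known limitations

- The trajectory assumes the lineage structure is tree-like at the
  cluster level; over-clustered data can add spurious leaves (the
  pipeline then tests the two most populated branches and folds the rest
  into the trunk).
- The permutation test compares only the two cycle modules; it does not
  produce G1/S/G2M phase assignments, and a cell elevating both modules
  equally is called non-proliferative by construction.
- Branch-test power depends on the fixed-dispersion approximation; for
  very low counts the Gaussian fallback is noticeably less powerful.
- GO/KEGG enrichment and multi-dataset integration are out of scope; the
  gene lists that would feed enrichment are exported as tables.
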