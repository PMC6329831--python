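# Methods

This note documents the models and procedures implemented in `cortexpipe`,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Data model

The pipeline's currency is `CountMatrix`: a sparse genes × cells matrix of
UMI counts with per-gene metadata (symbol, length in bases, mitochondrial
flag, species) and per-cell metadata (barcode, batch/replicate). On disk it
is the MatrixMarket trio (`matrix.mtx`, `genes.tsv`, `barcodes.tsv`);
genes are rows everywhere.

## Quality control

- **Species/doublet calls** (barnyard designs): a barcode with fewer than
  500 cross-species transcripts is discarded; otherwise it is called for a
  species only when that species holds *strictly more than* 90% of its
  transcripts, else it is a doublet. Both thresholds are exposed
  (`--min-total`, `--species-purity`).
- **Cell filter**: cells with fewer than 500 detected genes (count > 0) or
  a mitochondrial transcript share *strictly above* 10% are removed.
  "Exceeded" is read as strict, so a share of exactly 0.10 is retained.
  Mitochondrial genes are identified by the metadata flag, not a symbol
  prefix, so simulations can designate them.
- **Gene filter** (after the cell filter): genes detected in ≥ 10 cells
  with ≥ 60 transcripts total are kept; both boundaries inclusive.
  Each filter is idempotent; the composition cells-then-genes is the
  pipeline order (re-running the cell filter after gene removal could, in
  principle, drop further cells and is not done).
- **Normalization**: counts are scaled per cell to the median pre-scaling
  cell total, then log(1 + x). The median target is arbitrary but matches
  common droplet practice; all downstream statistics are scale-free or
  rank-based.
- **Batch adjustment**: per gene, each batch's values are Z-standardized
  and re-anchored to the gene's pooled mean and standard deviation — a
  location-scale adjustment without empirical-Bayes shrinkage across genes.
  It exactly removes the additive-in-log batch effects the simulator
  plants and leaves per-gene between-batch mean differences at 0 (within
  1e-8). A shrinkage estimator (ComBat-style) can be swapped in behind the
  same signature; shrinkage matters most for small batches, which the
  desk-scale simulations do not exercise. Zero-variance genes within a
  batch get a location-only shift; single-batch input is the identity.

## Dimensionality reduction

Genes are standardized to mean 0, sd 1 with the population (divide-by-n)
convention, applied consistently; constant genes are dropped with a logged
notice. Significant PCs are chosen by parallel analysis: every gene's
values are permuted independently across cells (destroying gene–gene
correlation, preserving marginals), eigenvalues are recomputed (default 500
permutations, 100 minimum), and observed PC *r* is significant when its
eigenvalue exceeds the 95th percentile of the permuted rank-*r*
eigenvalues. The retained dimensionality is the leading run of significant
PCs; the percentile and the permutation record are stored in the
`Embedding` for audit. A percentile criterion (not the permutation
maximum) was chosen and is configurable. The returned coordinates keep a
floor of 3 columns even when fewer PCs are significant, because the
rank-correlation distances used downstream are undefined on one- or
two-dimensional coordinate vectors; `n_significant` always reports the
true count. Eigenvalues are computed through the smaller Gram matrix, so
total variance equals the number of standardized genes exactly.

## Clustering and refinement

- **Distances for silhouettes**: d(i,j) = 1 − Spearman ρ between the two
  cells' PC coordinate vectors, computed on the clustering space (the
  embedding). Constant coordinate vectors have undefined rank correlation
  and get distance 1 to all non-identical cells, logged.
- **Graph**: for each cell the k Euclidean nearest neighbors (self
  excluded); edges join kNN pairs with Jaccard weight
  |N(i)∩N(j)| / |N(i)∪N(j)|; zero-overlap pairs are omitted.
- **Communities**: Louvain multilevel modularity at resolution 1
  (python-igraph), seeded deterministically.
- **Neighborhood scan**: k from 10 to 100 (stride configurable). A k
  yielding a single community records a missing silhouette and cannot be
  selected. Ties break toward the smallest k.
- **Refinement** (5 iterations): extreme outliers are cells with width
  < −0.1. Per iteration, per source cluster in ascending id order, the
  cluster's unflagged outliers are pooled; a pool of ≥ 10 cells whose mean
  silhouette as a tentative new cluster is strictly positive becomes a
  novel cluster, otherwise each pooled cell moves to its silhouette
  neighbor ("next-best") cluster. Widths are recomputed once per iteration
  after all moves (batch semantics keep the procedure order-insensitive
  within an iteration); moved cells still below the threshold revert to
  their original cluster and are flagged permanently. The history records
  every move, novel-cluster formation, and revert-flag event. Note that
  under per-cluster pooling a coherent outlier group can only form a novel
  cluster if at least `min_novel` of its cells share a source cluster;
  outliers scattered across clusters move individually instead.

## Markers and enrichment

Per cluster, genes are ranked by log2((mean_in + 1) / (mean_out + 1)) of
normalized expression; a two-sided binomial test compares the in-cluster
detection count to the outside detection fraction, with Benjamini–Hochberg
adjustment within cluster. The test statistic is pluggable; the binomial
detection test is the minimal choice consistent with droplet-era marker
callers. Gene-set enrichment is the one-sided hypergeometric upper tail
against a user-supplied universe, BH-adjusted across sets, with a report
flag for FDR < 0.1 and rank ≤ 50. A log-fold-change of 1.5 is the
conventional reporting threshold for cell-type markers.

## Sub-clustering

Candidate genes are detected in 25–75% (inclusive) of the cluster's cells.
Each is scored by its **excess dropout**: the gene's observed zero fraction
minus the expected zero fraction under a per-cell Poisson baseline at the
gene's own mean (de-logged) expression and the cell's relative depth, in
binomial standard deviations. A gene switched on in only a subset of cells
carries far more zeros than its mean predicts, so state-program genes
outrank uniformly expressed genes of equal mean; a naive variance of the
0/1 detection indicators cannot make this distinction, since a Bernoulli
variance is pinned by its mean. The top half of eligible genes by score is
retained (configurable). Cells are then clustered hierarchically
(1 − Pearson, complete linkage) on the selected genes; the dendrogram is
cut into 2–6 groups and the cut maximizing mean silhouette is accepted only
if that mean exceeds 0.1 and every group has ≥ 10 cells, otherwise the
cluster is reported homogeneous. The silhouette gate replaces manual
inspection of the heatmaps; its threshold is configurable and logged.
Accepted groups report gene modules (selected genes with positive
log-fold-change in the group).

## Pseudotime

Genes with TPM-like abundance ≥ 2 in ≥ 10 cells enter the embedding
("TPM" for UMI data is per-cell-total-scaled counts × 1e6 / total). A
single principal curve is fit through PC space by iterated
projection/smoothing: local-linear loess (tricube weights, span 0.5) of
each coordinate against the current pseudotime on a 100-point grid, then
re-projection of every cell onto the polyline; pseudotime is the
normalized arc length. Convergence is declared when the mean
projected-point displacement falls below 1e-4 (or 50 iterations; on
PC-scale coordinates the absolute tolerance is often not reached and the
last iterate is used with a warning — recovery quality is unaffected).
The endpoint constraint is implemented as initialization of pseudotime
along the axis joining the two endpoint-cluster medoids plus a final
orientation check (start cluster near 0). Hard-clamping the curve's
extremities to the medoids was considered and rejected: a clamped
extremity kinks the polyline and breaks the exact straight-line limit.
Gene curves over pseudotime use the same loess on Z-scored expression,
evaluated on a 100-point grid.

## Comparative analyses

Cluster profiles are per-gene arithmetic means of normalized expression.
Cross-dataset cell-type comparison uses Spearman correlation on a shared
marker-gene subset (robust to platform scale), drawing links only above a
user-set threshold (`min_rho` is required configuration; no default is
implied by the method). Cross-age comparison within one platform uses
1 − Pearson distances with complete linkage, serialized as Newick.
Cross-species gene mapping is reduced to a user-supplied two-column symbol
map. Gene-length bias is the Spearman correlation of a profile with gene
length.

## Disease subtyping and association

Gene profiles across the 44 combined clusters are median-centered per gene,
clustered on 1 − Pearson distance with complete linkage (linkage is
configurable; complete is the default of the hierarchical-heatmap ecosystem
this procedure comes from), and cut at a fixed height — 1.5 by default,
1.25 for panels tagged ASD. Subgroups with fewer than 3 genes are excluded
from association but reported. Each subgroup is collapsed to 15 broad
categories (per age: layer-specific neuron, interneuron, progenitor-like,
and non-neuronal classes) by a nested median — per gene across the
category's clusters, then across the subgroup's genes; the category map is
required configuration with a documented default for the simulator's 44
pseudo-clusters. The contingency table counts genes per (subtype,
phenotype); a gene with several phenotype annotations increments each of
its columns; genes with no annotations contribute nothing (zero rows or
columns are dropped with a notice). The two-sided test simulates the
fixed-margin null with Patefield sampling (10,000 replicates by default)
and uses the add-one estimator p = (1 + #{P(T) ≤ P(obs)}) / (1 + n_mc),
where P is the multivariate hypergeometric table probability; this
converges to the exact two-sided Fisher p on enumerable tables.

## Synthetic data

The generators produce every input the pipeline consumes, with planted
ground truth for recovery testing. All counts are negative binomial in the
mean/dispersion parameterization (variance μ + μ²/θ, θ = 2 by default).

- **`simulate_dge`** (default 600 cells × 2000 genes, 3 clusters, 3
  batches): a shared log-normal base profile (log-sd 1.5); per cluster,
  10% of genes perturbed by N(0, 1) log-fold-changes; cell library sizes
  log-normal around 2500 transcripts (the median depth of the emulated
  experiments); multiplicative per-batch gene effects with log-sd 0.15;
  3% doublets averaging two cluster profiles; 2% of genes flagged
  mitochondrial. Sparsity exceeds 0.5 at defaults.
- **`simulate_barnyard`**: singlets draw ≥ 95% of transcripts from their
  species (contamination uniform on [0, 0.05]); doublets mix species at a
  Uniform(0.25, 0.75) fraction so they are detectable at the 90% purity
  rule; the spike-in fraction defaults to 3%.
- **`simulate_trajectory_dge`**: latent t ~ Uniform(0,1); 40% of genes
  follow monotone (log-linear) or sigmoidal mean curves in t, the rest are
  flat. Genes follow their own rate curves with one global scale — per-cell
  compositional normalization was deliberately avoided because it couples
  flat genes to the dynamic ones and corrupts the planted null.
- **`simulate_state_cluster`**: one cell type with a bimodal program
  (default 30 genes, active in 40% of cells at log-fold-change 2). Program
  genes are planted among moderately detected genes (off-state detection
  probability in (0.1, 0.55)) so that the on/off split lands in the
  25–75% detection window — emulating a program that is observable through
  dropout patterns, as cell-cycle-like programs are.
- **`simulate_disease_panel`**: each gene inherits one of k subtype
  templates over 44 pseudo-clusters plus N(0, 0.35) noise. Default
  templates are cell-class peaked (amplitude 1.5 in the subtype's own
  cluster block, depressed elsewhere) with a per-gene reciprocal depletion
  (−1.2) in one specific other class, cycling within the subtype. The
  reciprocal structure mirrors real cell-type-specific genes (e.g.
  neuronal genes lowest in progenitors) and is what makes distinct
  subtypes strongly anticorrelated — mutually independent Gaussian
  templates can never exceed the 1.5 correlation-distance cut for k > 2,
  because equal pairwise template correlations are bounded below by
  −1/(k−1). Phenotype labels are drawn at base probability 0.3, raised
  toward 0.95 for the subtype's preferred phenotype in proportion to
  `association_strength` (0 = exact independence).

What the generators do **not** emulate: ambient RNA, bead-barcode errors
and UMI collapsing artifacts, empirical mean–variance trends (θ is constant
across genes), gene–gene co-expression beyond the planted cluster/state/
trajectory structure, batch effects that are non-multiplicative, and
realistic gene-length–expression coupling (lengths are independent draws).
Passing recovery tests therefore demonstrates correctness of the
procedures under their stated assumptions, not performance on real tissue.

## Determinism and problem sizes

All randomness flows from explicit seeds; the pipeline derives per-stage
seeds as sha256(global_seed, stage) so disabling one stage never shifts
another's stream. Louvain is seeded through Python's `random` module
(which python-igraph uses). Reruns are byte-identical. The test-suite and
acceptance-script problem sizes (hundreds of cells, 300–2000 genes, 100
permutations where the default is 500) are desk-scale choices that keep
the planted effects comfortably detectable; the defaults written into the
code are the emulated experiment's values.

## Known limitations

- The refinement's novel-cluster path requires outliers to share a source
  cluster (per-cluster pooling); a coherent group split across clusters is
  moved cell-wise instead.
- The location-scale batch adjustment assumes batch effects are shared
  across cells within a batch and ignores gene-wise shrinkage.
- The principal curve is single-lineage; branching trajectories are out of
  scope.
- The exact composition of the 15 disease-summary categories, and the
  handling of genes with no phenotype annotations, are configuration
  decisions surfaced to the user rather than fixed by the method.
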