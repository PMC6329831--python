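# cortexpipe

A tested, reusable reimplementation of the analysis pipeline used in
droplet-based (Drop-seq) single-cell studies of the developing mouse
neocortex: species/doublet filtering from barnyard designs, cell and gene
quality control, permutation-based selection of significant principal
components, Louvain–Jaccard graph clustering with silhouette-optimized
neighborhood selection and iterative outlier-reassignment refinement,
within-cluster sub-state detection, endpoint-constrained pseudotime,
cross-dataset cell-type correlation, and expression-based subtyping of
disease gene panels with Monte Carlo Fisher phenotype association.

The package is aimed at computational biologists who want these procedures
as importable, unit-tested functions rather than one-off analysis scripts —
and at anyone who wants to study the procedures' behavior on synthetic data
with planted ground truth, which the `synthetic` module generates as
first-class, tested code.

## The methods in brief

**Clustering.** Cells are embedded in PC space (components kept by
parallel analysis: each gene shuffled independently across cells, 500
permutations; PC *r* is significant when its eigenvalue exceeds the 95th
percentile of permuted rank-*r* eigenvalues). For each neighborhood size
*k* ∈ [10, 100], a *k*-nearest-neighbor graph with Jaccard edge weights
w(i,j) = |N(i)∩N(j)| / |N(i)∪N(j)| is clustered by Louvain modularity
maximization; the *k* maximizing the mean silhouette width
s(i) = (b(i) − a(i)) / max(a(i), b(i)) — on Spearman correlation distances
d(i,j) = 1 − ρ(xᵢ, xⱼ) between cells' PC coordinate vectors — is kept.
Over five refinement iterations, extreme outliers (s(i) < −0.1) of each
cluster either form a novel cluster (≥ 10 cells with positive tentative
silhouette) or move to their next-best cluster; cells that stay outliers
after moving revert and are flagged.

**Disease subtyping.** Disease genes are hierarchically clustered
(1 − Pearson, complete linkage) on median-centered expression across the 44
combined clusters (two ages × 22 types); the dendrogram is cut at height
1.5 (1.25 for ASD panels), subgroups with < 3 genes are excluded, each
subgroup is collapsed to 15 broad-category medians, and subtype × phenotype
contingency tables are tested with a two-sided Fisher-style test whose null
is 10,000 fixed-margin (Patefield) random tables:
p = (1 + #{P(T) ≤ P(obs)}) / (1 + n_mc).

## Worked example

Simulate a three-cluster cortex-like dataset and run all eight stages:

```bash
cortexpipe simulate dge --out sim --seed 42
printf 'n_permutations: 100\nk_step: 5\nn_mc: 2000\n' > cfg.yaml
cortexpipe run --config cfg.yaml --out run --seed 42
```

which prints `wrote 2000 genes x 600 cells to sim` and
`pipeline complete: run`. Inspecting the outputs:

```
>>> clusters.tsv: clusters {2: 201, 1: 199, 0: 195}, k_used 25
>>> mean silhouette 0.103, flagged cells 0
>>> disease_p_value.txt: 0.0469765
>>> k_scan.tsv (head):
 k  n_clusters  mean_silhouette
10           3         0.102189
15           3         0.102597
20           3         0.102773
```

The scan found three communities at every neighborhood size and kept
k = 25, the argmax of the mean silhouette; the 595 post-QC cells split
into three clusters matching the planted proportions; refinement found no
extreme outliers to reassign (the blobs are clean at this noise level); and
the simulated disease panel's subtype–phenotype association is significant
at p ≈ 0.047 under the 2,000-replicate Monte Carlo null requested in
`cfg.yaml`.

The same steps are available as library calls (`cortexpipe.synthetic`,
`cortexpipe.qc`, `cortexpipe.dimred`, `cortexpipe.clustering`, …); see
`docs/methods.md` for the model and parameter details.

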