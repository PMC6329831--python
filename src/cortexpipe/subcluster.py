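"""Within-cluster sub-type/state detection from heterogeneously detected genes.

Candidate genes are those detected in 25-75% of a cluster's cells; each is
scored by its excess dropout relative to a depth-aware Poisson baseline at
the gene's own mean expression.  A gene switched on in only a subset of
cells carries far more zeros than its mean predicts, so state-program genes
outrank genes whose detection merely tracks expression level and
sequencing depth.  Cells are then hierarchically clustered on the selected
genes and the dendrogram cut is accepted only when it is
silhouette-coherent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .clustering import silhouette_widths

logger = logging.getLogger(__name__)

MIN_DETECTION_FRACTION = 0.25
MAX_DETECTION_FRACTION = 0.75
MIN_SUBCLUSTER_SIZE = 10
ACCEPT_MEAN_SILHOUETTE = 0.1


@dataclass
class SubclusterResult:
    cluster: object
    genes: pd.DataFrame  # gene, detection_fraction, score
    labels: np.ndarray | None  # per-cell sub-cluster ids, or None for "none"
    modules: dict = field(default_factory=dict)  # sub-cluster id -> gene list


def heterogeneous_genes(
    x: np.ndarray,
    gene_names: list[str] | None = None,
    min_frac: float = MIN_DETECTION_FRACTION,
    max_frac: float = MAX_DETECTION_FRACTION,
    top_fraction: float = 0.5,
) -> pd.DataFrame:
    """Score genes with intermediate detection for state-like bimodality.

    ``x`` is the cluster's genes x cells log-normalized submatrix.  Eligible
    genes have detection fraction in [min_frac, max_frac] (inclusive).  The
    score is the gene's excess dropout over a per-cell Poisson baseline at
    its mean (de-logged) expression, in binomial standard deviations; a
    bimodal state gene has many more zeros than its mean predicts.  The
    ``top_fraction`` highest-scoring eligible genes are returned (at least
    2 when any are eligible).
    """
    x = np.asarray(x, dtype=float)
    n_genes, n_cells = x.shape
    if n_cells < 20:
        raise ValueError("sub-clustering needs at least 20 cells")
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    detected = x > 0
    frac = detected.mean(axis=1)
    eligible = (frac >= min_frac) & (frac <= max_frac)
    if not eligible.any():
        logger.info("no genes in the heterogeneous detection window")
        return pd.DataFrame(columns=["gene", "detection_fraction", "score"])

    vals = np.expm1(x)  # back to the scaled-count scale
    depth = vals.sum(axis=0)
    med = np.median(depth)
    s = depth / med if med > 0 else np.ones(n_cells)
    rows = []
    for g in np.flatnonzero(eligible):
        lam = vals[g].mean() / max(s.mean(), 1e-12)
        p0 = np.exp(-lam * s)  # expected per-cell dropout at this mean
        d_exp = p0.mean()
        d_obs = 1.0 - frac[g]
        sd = np.sqrt(max((p0 * (1 - p0)).mean() / n_cells, 1e-12))
        rows.append(
            {
                "gene": gene_names[g],
                "detection_fraction": frac[g],
                "score": float((d_obs - d_exp) / sd),
            }
        )
    table = pd.DataFrame(rows).sort_values("score", ascending=False, kind="stable")
    n_keep = max(2, int(np.ceil(top_fraction * len(table))))
    return table.head(n_keep).reset_index(drop=True)


def detect_subclusters(
    x: np.ndarray,
    genes: pd.DataFrame,
    gene_names: list[str],
    cluster_id: object = None,
    min_size: int = MIN_SUBCLUSTER_SIZE,
    max_groups: int = 6,
    accept_silhouette: float = ACCEPT_MEAN_SILHOUETTE,
) -> SubclusterResult:
    """Hierarchically cluster cells on the selected genes and gate the cut.

    Complete-linkage clustering on 1 - Pearson correlation distances between
    cells; the dendrogram is cut into 2..max_groups groups and the partition
    maximizing mean silhouette (same distances) is accepted only when that
    mean exceeds ``accept_silhouette`` and every group has ``min_size``
    cells; otherwise the cluster is reported homogeneous (labels None).

    Per accepted group, the gene module is the selected genes with positive
    log fold-change in that group.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 heterogeneous genes")
    x = np.asarray(x, dtype=float)
    name_to_row = {g: i for i, g in enumerate(gene_names)}
    rows = [name_to_row[g] for g in genes["gene"]]
    sub = x[rows, :]  # selected genes x cells

    cells = sub.T
    sd = cells.std(axis=1)
    if (sd == 0).all() or len(np.unique(cells, axis=0)) == 1:
        return SubclusterResult(cluster=cluster_id, genes=genes, labels=None)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(cells)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0

    Z = linkage(squareform(d, checks=False), method="complete")
    best_labels, best_sil = None, -np.inf
    for g in range(2, max_groups + 1):
        labels = fcluster(Z, t=g, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        widths, _ = silhouette_widths(d, labels)
        if widths.mean() > best_sil:
            best_sil, best_labels = float(widths.mean()), labels

    if (
        best_labels is None
        or best_sil <= accept_silhouette
        or min(np.bincount(best_labels)[1:]) < min_size
    ):
        return SubclusterResult(cluster=cluster_id, genes=genes, labels=None)

    modules = {}
    for grp in np.unique(best_labels):
        inside = best_labels == grp
        lfc = np.log2((sub[:, inside].mean(axis=1) + 1.0) / (sub[:, ~inside].mean(axis=1) + 1.0))
        modules[int(grp)] = [g for g, f in zip(genes["gene"], lfc) if f > 0]
    return SubclusterResult(cluster=cluster_id, genes=genes, labels=best_labels, modules=modules)
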