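"""Neighborhood-size scan, Louvain-Jaccard community detection, and
silhouette-driven cluster refinement.

The clustering procedure scans k-nearest-neighbor graph sizes (default 10 to
100), runs Louvain modularity optimization on the Jaccard-weighted shared
nearest-neighbor graph at each k, and keeps the k whose partition maximizes
the mean silhouette width computed on Spearman correlation distances between
cells' PC coordinate vectors.  A refinement pass then gives extreme outlier
cells (silhouette < -0.1) five chances to either form a novel cluster or
join their next-best cluster, flagging cells that fail to improve.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

OUTLIER_THRESHOLD = -0.1
REFINE_ITERATIONS = 5
MIN_NOVEL_SIZE = 10
K_MIN, K_MAX = 10, 100


@dataclass
class NeighborGraph:
    """Jaccard-weighted shared-nearest-neighbor graph over cells."""

    n_cells: int
    edges: np.ndarray  # (m, 2) int array of cell index pairs, i < j
    weights: np.ndarray  # (m,) Jaccard weights in (0, 1]
    k_neighbors: int

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_cells, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    silhouettes: np.ndarray
    flags: np.ndarray
    history: list = field(default_factory=list)
    k_used: int | None = None
    mean_silhouette: float = float("nan")


@dataclass
class ScanResult:
    records: list  # per-k dicts: k, n_clusters, mean_silhouette
    selected_k: int
    assignment: ClusterAssignment
    distance: np.ndarray


def spearman_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman correlation between cells' PC coordinate vectors.

    Cells whose coordinate vector is constant have undefined rank
    correlation; they get distance 1 to every non-identical cell.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] < 3:
        raise ValueError("need at least 3 PCs for rank correlations")
    ranks = rankdata(coords, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    safe = ranks.copy()
    if constant.any():
        logger.warning("%d cells have constant coordinate vectors", constant.sum())
        safe[constant] += np.arange(coords.shape[1])  # placeholder, overwritten below
    centered = safe - safe.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    corr = (centered @ centered.T) / np.outer(norm, norm)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    if constant.any():
        identical = np.isclose(coords[:, None, :], coords[None, :, :]).all(axis=2)
        for i in np.flatnonzero(constant):
            d[i, :] = np.where(identical[i], 0.0, 1.0)
            d[:, i] = d[i, :]
    np.fill_diagonal(d, 0.0)
    return d


def build_jaccard_knn(coords: np.ndarray, k: int) -> NeighborGraph:
    """k-nearest-neighbor graph with Jaccard overlap weights.

    Neighbor sets are the k Euclidean nearest neighbors (self excluded); an
    edge joins every kNN pair with weight |N(i) n N(j)| / |N(i) u N(j)|,
    dropping zero-overlap pairs.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_idx = idx[:, 1:]  # drop self
    return _jaccard_graph_from_neighbors(neighbor_idx, n, k)


def _jaccard_graph_from_neighbors(neighbor_idx: np.ndarray, n: int, k: int) -> NeighborGraph:
    import scipy.sparse as sp

    rows = np.repeat(np.arange(n), neighbor_idx.shape[1])
    adj = sp.csr_matrix(
        (np.ones(rows.size), (rows, neighbor_idx.ravel())), shape=(n, n), dtype=np.float64
    )
    cand = ((adj + adj.T) > 0).tocoo()  # kNN relation pairs
    mask = cand.row < cand.col
    ii, jj = cand.row[mask], cand.col[mask]
    inter = np.asarray(adj[ii].multiply(adj[jj]).sum(axis=1)).ravel()
    union = 2 * k - inter
    w = inter / union
    keep = w > 0
    return NeighborGraph(
        n_cells=n,
        edges=np.column_stack([ii[keep], jj[keep]]),
        weights=w[keep],
        k_neighbors=k,
    )


def detect_communities(g: NeighborGraph, seed: int = 0) -> np.ndarray:
    """Louvain multilevel modularity communities at resolution 1."""
    if g.n_cells == 0:
        raise ValueError("empty graph")
    graph = g.to_igraph()
    _pyrandom.seed(seed)  # igraph draws from Python's random module
    part = graph.community_multilevel(weights="weight")
    return np.asarray(part.membership)


def silhouette_widths(d: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell silhouette widths and the neighbor ("next-best") cluster.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean within-cluster
    distance excluding self and b(i) the smallest mean distance to another
    cluster.  Cells in singleton clusters get width 0.

    Returns ``(widths, neighbor_cluster)``.
    """
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("silhouettes need at least 2 clusters")
    n = len(labels)
    onehot = np.zeros((n, len(uniq)))
    onehot[np.arange(n), inv] = 1.0
    counts = onehot.sum(axis=0)
    sums = d @ onehot  # mean-dist numerators to each cluster
    own = inv
    own_counts = counts[own]
    a = np.where(own_counts > 1, sums[np.arange(n), own] / np.maximum(own_counts - 1, 1), 0.0)
    means_other = sums / counts[None, :]
    means_other[np.arange(n), own] = np.inf
    neighbor = np.argmin(means_other, axis=1)
    b = means_other[np.arange(n), neighbor]
    with np.errstate(invalid="ignore"):
        s = (b - a) / np.maximum(a, b)
    s = np.where(own_counts == 1, 0.0, np.nan_to_num(s, nan=0.0))
    return s, uniq[neighbor]


def scan_neighborhood_sizes(
    coords: np.ndarray,
    k_min: int = K_MIN,
    k_max: int = K_MAX,
    k_step: int = 1,
    seed: int = 0,
    distance: np.ndarray | None = None,
) -> ScanResult:
    """Scan k over [k_min, k_max], cluster at each k, select by mean silhouette.

    Silhouettes use Spearman correlation distances between cells' PC
    vectors.  ks producing a single community are recorded with a missing
    mean silhouette and are ineligible; ties break toward the smallest k.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of cells")
    if distance is None:
        distance = spearman_distance_matrix(coords)

    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    all_neighbors = idx[:, 1:]

    records = []
    best: tuple[float, int] | None = None
    best_labels = None
    for k in range(k_min, k_max + 1, k_step):
        graph = _jaccard_graph_from_neighbors(all_neighbors[:, :k], n, k)
        labels = detect_communities(graph, seed=seed)
        n_clusters = len(np.unique(labels))
        if n_clusters < 2:
            records.append({"k": k, "n_clusters": n_clusters, "mean_silhouette": float("nan")})
            continue
        widths, _ = silhouette_widths(distance, labels)
        mean_sil = float(widths.mean())
        records.append({"k": k, "n_clusters": n_clusters, "mean_silhouette": mean_sil})
        if best is None or mean_sil > best[0]:
            best = (mean_sil, k)
            best_labels = labels
    if best is None:
        raise ValueError("every k yielded a single community; no selectable clustering")

    widths, _ = silhouette_widths(distance, best_labels)
    assignment = ClusterAssignment(
        labels=best_labels,
        silhouettes=widths,
        flags=np.zeros(n, dtype=bool),
        k_used=best[1],
        mean_silhouette=best[0],
    )
    return ScanResult(records=records, selected_k=best[1], assignment=assignment, distance=distance)


def refine_assignments(
    d: np.ndarray,
    initial: ClusterAssignment,
    n_iter: int = REFINE_ITERATIONS,
    outlier_threshold: float = OUTLIER_THRESHOLD,
    min_novel: int = MIN_NOVEL_SIZE,
) -> ClusterAssignment:
    """Iteratively reassign extreme outlier cells (width < threshold).

    Per iteration, per source cluster in ascending id order, the cluster's
    unflagged outliers are pooled: a pool of at least ``min_novel`` cells
    whose mean silhouette as a tentative new cluster is positive becomes a
    novel cluster; otherwise each pooled cell joins its next-best (silhouette
    neighbor) cluster.  After the iteration's moves, widths are recomputed;
    moved cells still below threshold revert to their original cluster and
    are flagged, never to move again.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    labels = np.asarray(initial.labels).copy()
    flags = (
        np.asarray(initial.flags).copy()
        if initial.flags is not None
        else np.zeros(len(labels), dtype=bool)
    )
    history: list[dict] = []

    for it in range(n_iter):
        widths, neighbor = silhouette_widths(d, labels)
        start_labels = labels.copy()
        outlier = (widths < outlier_threshold) & ~flags
        if not outlier.any():
            break
        moved: list[tuple[int, int]] = []  # (cell, original cluster)
        next_label = int(labels.max()) + 1
        for c in np.unique(start_labels):
            pool = np.flatnonzero((start_labels == c) & outlier)
            if pool.size == 0:
                continue
            if pool.size >= min_novel:
                tentative = labels.copy()
                tentative[pool] = next_label
                t_widths, _ = silhouette_widths(d, tentative)
                if float(t_widths[pool].mean()) > 0.0:
                    labels = tentative
                    for cell in pool:
                        history.append(
                            {"iter": it, "cell": int(cell), "event": "novel",
                             "from": int(c), "to": next_label}
                        )
                    next_label += 1
                    continue
            for cell in pool:
                history.append(
                    {"iter": it, "cell": int(cell), "event": "move",
                     "from": int(c), "to": int(neighbor[cell])}
                )
                labels[cell] = neighbor[cell]
                moved.append((int(cell), int(c)))
        widths_after, _ = silhouette_widths(d, labels)
        for cell, origin in moved:
            if widths_after[cell] < outlier_threshold:
                labels[cell] = origin
                flags[cell] = True
                history.append(
                    {"iter": it, "cell": cell, "event": "revert_flag",
                     "from": int(labels[cell]), "to": origin}
                )

    final_widths, _ = silhouette_widths(d, labels)
    return ClusterAssignment(
        labels=labels,
        silhouettes=final_widths,
        flags=flags,
        history=history,
        k_used=initial.k_used,
        mean_silhouette=float(final_widths.mean()),
    )
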