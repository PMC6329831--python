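"""Gene-wise standardization, PCA and permutation selection of significant PCs.

The number of components to retain is chosen by parallel analysis: each
gene's values are shuffled independently across cells (destroying gene-gene
correlation while preserving marginals), eigenvalues are recomputed, and an
observed PC is significant when its eigenvalue exceeds the 95th percentile
of the permuted eigenvalues of the same rank.  The retained dimensionality
is the leading run of significant PCs.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import Embedding

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 500
SIGNIFICANCE_QUANTILE = 0.95


def zscore_genes(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each gene (row) to mean 0, sd 1 (population convention).

    Returns ``(z, kept_mask)``; constant genes are dropped with a notice.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd (ddof=0)
    kept = (sd > 0).ravel()
    if not kept.all():
        logger.info("dropping %d constant genes before standardization", (~kept).sum())
    z = (x[kept] - mean[kept]) / sd[kept]
    return z, kept


def _eigenvalues(z_cells_by_genes: np.ndarray) -> np.ndarray:
    """All covariance eigenvalues, descending, via the smaller Gram matrix."""
    n, p = z_cells_by_genes.shape
    if n <= p:
        gram = z_cells_by_genes @ z_cells_by_genes.T / n
    else:
        gram = z_cells_by_genes.T @ z_cells_by_genes / n
    ev = np.linalg.eigvalsh(gram)[::-1]
    return np.maximum(ev, 0.0)


def select_significant_pcs(
    x: np.ndarray,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    quantile: float = SIGNIFICANCE_QUANTILE,
    min_components: int = 3,
) -> Embedding:
    """Parallel-analysis PC selection on a standardized genes x cells matrix.

    Parameters
    ----------
    x
        Genes x cells standardized matrix (see :func:`zscore_genes`).
    n_perm
        Number of per-gene permutations (>= 100).
    quantile
        Rank-matched permuted-eigenvalue quantile an observed eigenvalue
        must exceed to be significant.
    min_components
        Floor on the number of returned coordinate columns (rank-based
        cell-cell distances downstream need at least 3); ``n_significant``
        itself is unaffected.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    data = x.T  # cells x genes
    n_cells = data.shape[0]

    # SVD once for observed eigenvalues and coordinates
    u, s, _ = np.linalg.svd(data - data.mean(axis=0), full_matrices=False)
    eigenvalues = s**2 / n_cells
    coords_full = u * s

    n_ev = len(eigenvalues)
    perm_ev = np.empty((n_perm, n_ev))
    shuffled = data.copy()
    for r in range(n_perm):
        shuffled = rng.permuted(shuffled, axis=0)  # each gene shuffled across cells
        perm_ev[r] = _eigenvalues(shuffled)[:n_ev]
    thresholds = np.quantile(perm_ev, quantile, axis=0)

    significant = eigenvalues > thresholds
    n_significant = 0
    for flag in significant:
        if not flag:
            break
        n_significant += 1
    if n_significant == 0:
        raise ValueError(
            "no principal component exceeds the permutation threshold; "
            "inspect the input for structure before reducing it"
        )
    n_keep = min(max(n_significant, min_components), n_ev)
    return Embedding(
        coordinates=coords_full[:, :n_keep],
        eigenvalues=eigenvalues,
        n_significant=n_significant,
        permutation_quantiles=thresholds,
        n_permutations=n_perm,
    )
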