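"""Cluster-profile collapse and within/cross-dataset cell-type correlation.

Cross-dataset comparisons use Spearman correlation on a shared marker-gene
subset (robust to platform scale); cross-age comparisons within one
platform use Pearson correlation distances with complete-linkage
hierarchical clustering, serialized as Newick.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io import linkage_to_newick

MIN_SHARED_GENES = 5


def collapse_cluster_profiles(x: np.ndarray, labels: np.ndarray, gene_names: list[str],
                              tag: str | None = None) -> pd.DataFrame:
    """Per-cluster per-gene arithmetic mean of normalized expression.

    Returns a genes x clusters DataFrame; columns are cluster ids, prefixed
    with ``tag`` when given (e.g. the dataset or age label).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    cols = {}
    for c in np.unique(labels):
        name = f"{tag}:{c}" if tag is not None else c
        cols[name] = x[:, labels == c].mean(axis=1)
    return pd.DataFrame(cols, index=gene_names)


def cross_correlate_types(
    a: pd.DataFrame,
    b: pd.DataFrame,
    shared_genes: list[str],
    min_rho: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of profiles on the shared gene subset.

    Returns ``(rho_table, links)`` where links holds the (cluster_a,
    cluster_b, rho) pairs with rho strictly above ``min_rho``.
    """
    shared = [g for g in shared_genes if g in a.index and g in b.index]
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(f"need at least {MIN_SHARED_GENES} shared genes, got {len(shared)}")
    sub_a, sub_b = a.loc[shared], b.loc[shared]
    combined = np.hstack([sub_a.to_numpy(), sub_b.to_numpy()])
    rho, _ = spearmanr(combined)
    na = sub_a.shape[1]
    if combined.shape[1] == 2:  # spearmanr collapses two columns to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho_ab = np.asarray(rho)[:na, na:]
    table = pd.DataFrame(rho_ab, index=a.columns, columns=b.columns)
    links = (
        table.stack()
        .rename("rho")
        .reset_index()
        .set_axis(["cluster_a", "cluster_b", "rho"], axis=1)
    )
    links = links[links["rho"] > min_rho].reset_index(drop=True)
    return table, links


def cross_age_dendrogram(
    profiles: pd.DataFrame, genes: list[str] | None = None
) -> tuple[np.ndarray, str, pd.DataFrame]:
    """Complete-linkage dendrogram of profiles on 1 - Pearson distances.

    ``profiles`` is genes x clusters (both ages combined); ``genes``
    restricts to a marker-union subset when given.  Returns the linkage
    matrix, its Newick serialization, and the pairwise correlation table.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 profiles")
    sub = profiles.loc[[g for g in genes if g in profiles.index]] if genes is not None else profiles
    corr = np.corrcoef(sub.to_numpy().T)
    corr = np.nan_to_num(np.clip(corr, -1.0, 1.0), nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform((d + d.T) / 2.0, checks=False), method="complete")
    newick = linkage_to_newick(Z, [str(c) for c in profiles.columns])
    corr_table = pd.DataFrame(corr, index=profiles.columns, columns=profiles.columns)
    return Z, newick, corr_table


def gene_length_correlation(profile: pd.Series, lengths: pd.Series) -> float:
    """Spearman correlation between a cluster profile and gene length."""
    if not set(profile.index) <= set(lengths.index):
        raise ValueError("lengths missing for some profile genes")
    rho, _ = spearmanr(profile.to_numpy(), lengths.loc[profile.index].to_numpy())
    return float(rho)
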