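"""Cluster marker ranking and hypergeometric gene-set enrichment."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import binomtest, hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MARKER_LFC_REPORT = 1.5  # conventional reporting threshold for cell-type markers
ENRICHMENT_FDR = 0.1
ENRICHMENT_TOP_N = 50


def rank_markers(
    x: np.ndarray,
    labels: np.ndarray,
    gene_names: list[str] | None = None,
) -> pd.DataFrame:
    """Rank genes per cluster by log2 fold-change of mean normalized expression.

    For each (gene, cluster): lfc = log2((mean_in + 1) / (mean_out + 1)) on
    the normalized scale; a two-sided binomial test compares the in-cluster
    detection count against the outside detection fraction; p-values are
    Benjamini-Hochberg adjusted across genes within each cluster.  Genes are
    returned sorted by descending lfc within cluster.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("marker ranking needs at least 2 clusters")
    n_genes = x.shape[0]
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    detected = x > 0

    frames = []
    for c in uniq:
        inside = labels == c
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in == 1:
            logger.warning("cluster %s has a single cell; marker statistics are weak", c)
        mean_in = x[:, inside].mean(axis=1)
        mean_out = x[:, ~inside].mean(axis=1)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        det_in = detected[:, inside].sum(axis=1)
        frac_in = det_in / n_in
        frac_out = detected[:, ~inside].sum(axis=1) / n_out
        pvals = np.array(
            [
                binomtest(int(k), n_in, min(max(p, 1e-12), 1 - 1e-12)).pvalue
                for k, p in zip(det_in, frac_out)
            ]
        )
        padj = multipletests(pvals, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "gene": gene_names,
                "cluster": c,
                "lfc": lfc,
                "frac_in": frac_in,
                "frac_out": frac_out,
                "pvalue": pvals,
                "padj": padj,
            }
        ).sort_values("lfc", ascending=False, kind="stable")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def hypergeometric_enrichment(
    markers: set[str] | list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    fdr_threshold: float = ENRICHMENT_FDR,
    top_n: int = ENRICHMENT_TOP_N,
) -> pd.DataFrame:
    """One-sided hypergeometric (upper tail) enrichment of markers in each set.

    Reports BH-adjusted FDR across sets and flags sets with FDR below
    ``fdr_threshold`` that also rank in the ``top_n`` by p-value.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    markers = set(markers)
    if not markers <= universe_set:
        raise ValueError("markers must be a subset of the universe")
    N, n = len(universe_set), len(markers)

    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe_set
        K = len(members)
        k = len(markers & members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "pvalue": p})
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table = table.sort_values("pvalue", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["reported"] = (table["fdr"] < fdr_threshold) & (table["rank"] <= top_n)
    return table
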