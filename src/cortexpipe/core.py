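"""Shared in-memory containers for the pipeline.

The universal currency is :class:`CountMatrix`: a sparse genes x cells UMI
count matrix with per-gene and per-cell metadata, mirroring the on-disk
MatrixMarket + TSV-sidecar trio produced by droplet sequencing pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

GENE_META_COLUMNS = ("symbol", "length", "mito")
CELL_META_COLUMNS = ("barcode", "batch")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI counts plus aligned metadata tables.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes as rows, cells as columns.
    gene_meta
        One row per gene; must carry ``symbol`` (str), ``length`` (bases, > 0)
        and ``mito`` (bool) columns.  Extra columns (e.g. ``species``) pass
        through untouched.
    cell_meta
        One row per cell; must carry ``barcode`` (unique str) and ``batch``
        columns.  Extra columns (e.g. ``age``) pass through.
    """

    counts: sp.csr_matrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_meta), len(self.cell_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.gene_meta)} genes, {len(self.cell_meta)} cells)"
            )
        for col in GENE_META_COLUMNS:
            if col not in self.gene_meta.columns:
                raise ValueError(f"gene_meta missing required column {col!r}")
        for col in CELL_META_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if (self.gene_meta["length"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.cell_meta["barcode"].duplicated().any():
            raise ValueError("duplicate cell barcodes")
        self.gene_meta = self.gene_meta.reset_index(drop=True)
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            counts=self.counts[:, mask].tocsr(),
            gene_meta=self.gene_meta.copy(),
            cell_meta=self.cell_meta.loc[np.flatnonzero(mask) if mask.dtype == bool else mask].copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            counts=self.counts[mask, :].tocsr(),
            gene_meta=self.gene_meta.loc[np.flatnonzero(mask) if mask.dtype == bool else mask].copy(),
            cell_meta=self.cell_meta.copy(),
        )


@dataclass
class GroundTruth:
    """Planted labels emitted by the simulators, for recovery testing."""

    cell_labels: np.ndarray | None = None
    batch_labels: np.ndarray | None = None
    doublet_flags: np.ndarray | None = None
    state_labels: np.ndarray | None = None
    pseudotime: np.ndarray | None = None
    subtype_labels: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class Embedding:
    """Cells x retained-PC coordinates with the permutation record."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    n_significant: int
    permutation_quantiles: np.ndarray | None = None
    n_permutations: int = 0

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9 * max(1.0, abs(ev[0]) if len(ev) else 1.0)):
            raise ValueError("eigenvalues must be non-increasing")
        if self.n_significant > len(ev):
            raise ValueError("n_significant exceeds number of PCs")
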