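"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive O(n^2)/enumeration implementations,
kept independent of the library code paths they check.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cortexpipe.core import CountMatrix


# ---------------------------------------------------------------- oracles


def brute_force_silhouette(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Textbook per-point silhouette, one cell at a time."""
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        widths[i] = (b - a) / max(a, b)
    return widths


def enumerate_fisher_p(table: np.ndarray) -> float:
    """Exact two-sided Fisher p by enumerating all fixed-margin tables.

    Probability-based two-sidedness: sum the multivariate hypergeometric
    probabilities of all tables at most as probable as the observed one.
    Feasible for 2x2 and 2x3 tables.
    """
    table = np.asarray(table, dtype=int)
    rows, cols = table.sum(axis=1), table.sum(axis=0)

    def log_prob(t: np.ndarray) -> float:
        return (
            sum(math.lgamma(r + 1) for r in rows)
            + sum(math.lgamma(c + 1) for c in cols)
            - math.lgamma(t.sum() + 1)
            - sum(math.lgamma(v + 1) for v in t.ravel())
        )

    obs_lp = log_prob(table)
    # enumerate first row freely; second row forced by column margins
    ranges = [range(min(rows[0], c) + 1) for c in cols]
    total = 0.0
    for first in product(*ranges):
        first = np.array(first)
        if first.sum() != rows[0]:
            continue
        second = cols - first
        if (second < 0).any() or second.sum() != rows[1]:
            continue
        t = np.vstack([first, second])
        lp = log_prob(t)
        if lp <= obs_lp + 1e-9:
            total += math.exp(lp)
    return total


# ---------------------------------------------------------------- fixtures


def make_count_matrix(counts: np.ndarray, mito_flags=None, batches=None) -> CountMatrix:
    """Wrap a dense genes x cells array in a CountMatrix with minimal metadata."""
    counts = np.asarray(counts)
    g, c = counts.shape
    if mito_flags is None:
        mito_flags = np.zeros(g, dtype=bool)
    if batches is None:
        batches = ["rep0"] * c
    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(g)],
            "symbol": [f"Gene{i}" for i in range(g)],
            "length": np.full(g, 1000),
            "mito": np.asarray(mito_flags, dtype=bool),
        }
    )
    cell_meta = pd.DataFrame({"barcode": [f"BC{i}" for i in range(c)], "batch": batches})
    return CountMatrix(counts=sp.csr_matrix(counts), gene_meta=gene_meta, cell_meta=cell_meta)


def gaussian_blobs(
    rng: np.random.Generator,
    sizes: tuple[int, ...],
    n_dims: int = 10,
    center_scale: float = 3.0,
    noise: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated Gaussian blobs in a PC-like coordinate space.

    Centers are drawn at ``center_scale`` with tight ``noise`` around them,
    so both Euclidean and Spearman-rank distances separate the blobs."""
    centers = rng.normal(0.0, center_scale, size=(len(sizes), n_dims))
    coords, labels = [], []
    for b, size in enumerate(sizes):
        coords.append(centers[b] + rng.normal(0.0, noise, size=(size, n_dims)))
        labels.extend([b] * size)
    return np.vstack(coords), np.array(labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
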