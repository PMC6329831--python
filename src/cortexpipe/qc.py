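"""Species/doublet assignment, cell and gene filters, normalization, batch adjustment.

Thresholds follow standard droplet-sequencing practice for a species-mixing
(barnyard) design: barcodes under 500 total transcripts are discarded, a
barcode is called for a species only when >90% of its transcripts are
species-specific, and otherwise it is a doublet.  Cell filtering removes
cells with <500 detected genes or >10% mitochondrial transcripts; gene
filtering keeps genes seen in >=10 cells with >=60 transcripts in total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CountMatrix

logger = logging.getLogger(__name__)

MIN_BARNYARD_TOTAL = 500
SPECIES_PURITY = 0.90
MIN_GENES_PER_CELL = 500
MAX_MITO_FRACTION = 0.10
MIN_CELLS_PER_GENE = 10
MIN_TRANSCRIPTS_PER_GENE = 60


def assign_species(
    table: pd.DataFrame,
    min_total: int = MIN_BARNYARD_TOTAL,
    purity: float = SPECIES_PURITY,
) -> pd.DataFrame:
    """Call each barcode as species_a / species_b / doublet / discarded.

    A barcode is discarded when its cross-species transcript total is below
    ``min_total``; called for the major species when that species holds a
    fraction strictly above ``purity``; otherwise called a doublet.
    """
    a = np.asarray(table["transcripts_species_a"])
    b = np.asarray(table["transcripts_species_b"])
    if (a < 0).any() or (b < 0).any():
        raise ValueError("transcript counts must be non-negative")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_major = np.where(total > 0, np.maximum(a, b) / np.maximum(total, 1), 0.5)
    call = np.where(
        total < min_total,
        "discarded",
        np.where(
            (a / np.maximum(total, 1) > purity),
            "species_a",
            np.where(b / np.maximum(total, 1) > purity, "species_b", "doublet"),
        ),
    )
    return pd.DataFrame(
        {
            "barcode": table["barcode"].to_numpy(),
            "call": call,
            "fraction_major": frac_major,
            "total": total,
        }
    )


def filter_cells(
    m: CountMatrix,
    min_genes: int = MIN_GENES_PER_CELL,
    max_mito: float = MAX_MITO_FRACTION,
) -> CountMatrix:
    """Drop cells with fewer than ``min_genes`` detected genes or a
    mitochondrial transcript share strictly above ``max_mito``."""
    detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    mito_mask = m.gene_meta["mito"].to_numpy(dtype=bool)
    if not mito_mask.any():
        logger.warning("no mitochondrial-flagged genes; mito filter is vacuous")
        mito_share = np.zeros(m.n_cells)
    else:
        mito_totals = np.asarray(m.counts[mito_mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_share = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    keep = (detected >= min_genes) & (mito_share <= max_mito)
    return m.subset_cells(keep)


def filter_genes(
    m: CountMatrix,
    min_cells: int = MIN_CELLS_PER_GENE,
    min_transcripts: int = MIN_TRANSCRIPTS_PER_GENE,
) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells and
    totalling at least ``min_transcripts`` across all cells."""
    n_cells_detected = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    keep = (n_cells_detected >= min_cells) & (totals >= min_transcripts)
    return m.subset_genes(keep)


def normalize_log(m: CountMatrix) -> np.ndarray:
    """Scale each cell to the median pre-scaling cell total, then log1p.

    Returns a dense genes x cells array of normalized expression.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; apply filters first")
    target = float(np.median(totals))
    scaled = m.counts.multiply(target / totals[None, :]).toarray()
    return np.log1p(scaled)


def adjust_batches(x: np.ndarray, batches: np.ndarray) -> np.ndarray:
    """Location-scale batch adjustment of a genes x cells matrix.

    Per gene, each batch's values are Z-standardized and re-anchored to the
    gene's pooled mean and pooled standard deviation, removing additive and
    multiplicative batch effects on the (log) expression scale.  Genes with
    zero variance inside a batch receive a location-only shift.  This is a
    plain location-scale adjustment without empirical-Bayes shrinkage across
    genes; the interface accepts any adjuster with the same signature.
    """
    x = np.asarray(x, dtype=float)
    batches = np.asarray(batches)
    uniq = pd.unique(batches)
    if len(uniq) < 2:
        logger.info("single batch; adjustment is the identity")
        return x.copy()
    counts = pd.Series(batches).value_counts()
    if (counts < 2).any():
        raise ValueError("each batch needs at least 2 cells")

    pooled_mean = x.mean(axis=1, keepdims=True)
    pooled_sd = x.std(axis=1, keepdims=True)
    out = np.empty_like(x)
    for b in uniq:
        cols = batches == b
        sub = x[:, cols]
        bm = sub.mean(axis=1, keepdims=True)
        bs = sub.std(axis=1, keepdims=True)
        z = np.where(bs > 0, (sub - bm) / np.where(bs > 0, bs, 1.0), sub - bm)
        scale = np.where(bs > 0, pooled_sd, 1.0)
        out[:, cols] = pooled_mean + scale * z
    return out
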