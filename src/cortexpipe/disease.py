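"""Expression subtyping of disease gene panels and phenotype association.

Disease genes are grouped by hierarchical clustering of median-centered
expression across the 44 combined pseudo-clusters (two ages x 22 cell
types) with 1 - Pearson correlation distance, cutting the dendrogram at a
fixed height (default 1.5; 1.25 for panels tagged ASD).  Subgroups with
fewer than 3 genes are excluded from downstream association.  Association
between subtype membership and clinical phenotype labels uses a two-sided
Fisher-style test with a Monte Carlo null of fixed-margin random tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import random_table
from scipy.special import gammaln

logger = logging.getLogger(__name__)

DEFAULT_CUT_HEIGHT = 1.5
ASD_CUT_HEIGHT = 1.25
MIN_SUBGROUP_GENES = 3
DEFAULT_N_MC = 10000
N_SUMMARY_CATEGORIES = 15


@dataclass
class SubtypeResult:
    subgroups: dict  # subgroup id -> list of gene names (retained, >= 3 genes)
    excluded: list  # genes in subgroups smaller than the minimum
    linkage: np.ndarray
    cut_height: float
    summary: pd.DataFrame | None = None
    contingency: pd.DataFrame | None = None
    p_value: float | None = None
    n_mc: int = 0


def default_category_map(cluster_names: list[str]) -> dict:
    """Assign 44 combined clusters to 15 broad categories.

    The default emulates the broad-class collapse used for developing
    cortex: per age, clusters are grouped as layer-specific neuron,
    interneuron, progenitor-like, and non-neuronal classes (astrocyte-like,
    oligodendrocyte-like, microglia, vascular/other), giving roughly 15
    categories over two ages.  Real analyses should supply a curated map.
    """
    base = [
        "layer_neuron", "interneuron", "progenitor",
        "astrocyte", "oligodendrocyte", "microglia", "vascular",
    ]
    cats = [f"E14_{c}" for c in base] + [f"P0_{c}" for c in base] + ["other"]
    cats = cats[:N_SUMMARY_CATEGORIES]
    return {name: cats[i % len(cats)] for i, name in enumerate(cluster_names)}


def subtype_disease_genes(
    profiles: pd.DataFrame,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_genes: int = MIN_SUBGROUP_GENES,
    method: str = "complete",
) -> SubtypeResult:
    """Cut the median-centered-expression gene dendrogram into subgroups.

    ``profiles`` is genes x clusters normalized expression.  Each gene is
    median-centered across clusters; genes are clustered on 1 - Pearson
    correlation distance; flat subgroups are taken at ``cut_height``.
    Subgroups with fewer than ``min_genes`` genes are excluded from
    downstream association but reported.
    """
    if profiles.shape[0] < 4:
        raise ValueError("need at least 4 genes with profiles")
    x = profiles.to_numpy(dtype=float)
    x = x - np.median(x, axis=1, keepdims=True)

    sd = x.std(axis=1)
    corr = np.zeros((len(x), len(x)))
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(x[ok])
        corr[np.ix_(ok, ok)] = np.nan_to_num(np.atleast_2d(sub), nan=0.0)
    corr[np.arange(len(x)), np.arange(len(x))] = 1.0
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform((d + d.T) / 2.0, checks=False), method=method)
    flat = fcluster(Z, t=cut_height, criterion="distance")

    subgroups, excluded = {}, []
    for grp in np.unique(flat):
        members = [profiles.index[i] for i in np.flatnonzero(flat == grp)]
        if len(members) >= min_genes:
            subgroups[int(grp)] = members
        else:
            excluded.extend(members)
    return SubtypeResult(subgroups=subgroups, excluded=excluded, linkage=Z, cut_height=cut_height)


def summarize_subtype_profiles(
    profiles: pd.DataFrame,
    subgroups: dict,
    category_map: dict,
) -> pd.DataFrame:
    """Collapse each subgroup to one median value per broad category.

    Per gene, expression is median-collapsed across the clusters of each
    category; per subgroup, the member genes' category values are then
    median-collapsed, yielding a subgroups x categories summary (15 values
    per subgroup with the default category map).
    """
    categories = sorted(set(category_map.values()))
    for cat in categories:
        if not any(v == cat for v in category_map.values()):
            raise ValueError(f"category {cat!r} has no clusters")
    missing = [c for c in profiles.columns if c not in category_map]
    if missing:
        raise ValueError(f"clusters without a category: {missing[:5]}")

    x = profiles.to_numpy(dtype=float)
    x = x - np.median(x, axis=1, keepdims=True)
    centered = pd.DataFrame(x, index=profiles.index, columns=profiles.columns)

    per_gene = pd.DataFrame(index=profiles.index, columns=categories, dtype=float)
    for cat in categories:
        cols = [c for c in profiles.columns if category_map[c] == cat]
        if not cols:
            raise ValueError(f"category {cat!r} has no clusters")
        per_gene[cat] = centered[cols].median(axis=1)

    rows = {}
    for grp, members in subgroups.items():
        rows[grp] = per_gene.loc[members].median(axis=0)
    return pd.DataFrame(rows).T[categories]


def _log_table_probability(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given margins."""
    table = np.asarray(table, dtype=float)
    r, c = table.sum(axis=1), table.sum(axis=0)
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(table.sum() + 1)
        - gammaln(table + 1).sum()
    )


def build_contingency(subgroups: dict, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Subtype x phenotype gene counts; multi-label genes count once per
    phenotype column."""
    rows = {}
    for grp, members in subgroups.items():
        present = [g for g in members if g in phenotypes.index]
        rows[grp] = phenotypes.loc[present].sum(axis=0)
    table = pd.DataFrame(rows).T
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.info(
            "dropping %d zero rows and %d zero columns from the contingency table",
            (~keep_rows).sum(), (~keep_cols).sum(),
        )
    return table.loc[keep_rows, keep_cols]


def phenotype_association_test(
    subgroups: dict,
    phenotypes: pd.DataFrame,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Two-sided Fisher-style association via fixed-margin Monte Carlo.

    The null preserves both table margins (Patefield sampling of random
    tables); the two-sided p-value is the add-one estimate of the
    probability that a null table is at most as probable as the observed
    one: p = (1 + #{P(null) <= P(obs)}) / (1 + n_mc).
    """
    table = build_contingency(subgroups, phenotypes)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 subgroups and 2 phenotypes with nonzero counts")
    obs = table.to_numpy(dtype=int)
    return table, monte_carlo_fisher(obs, n_mc=n_mc, seed=seed)


def monte_carlo_fisher(observed: np.ndarray, n_mc: int = DEFAULT_N_MC, seed: int = 0) -> float:
    """Monte Carlo two-sided Fisher p for an r x c contingency table."""
    observed = np.asarray(observed, dtype=int)
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_probability(observed)
    sampler = random_table(observed.sum(axis=1), observed.sum(axis=0))
    tables = sampler.rvs(size=n_mc, method="patefield", random_state=rng)
    null_logp = (
        gammaln(observed.sum(axis=1) + 1).sum()
        + gammaln(observed.sum(axis=0) + 1).sum()
        - gammaln(observed.sum() + 1)
        - gammaln(tables + 1).sum(axis=(1, 2))
    )
    extreme = np.sum(null_logp <= obs_logp + 1e-7)
    return float((1 + extreme) / (1 + n_mc))
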