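"""Simulators producing every input the analysis consumes, with planted truth.

All counts are negative-binomial in the mean/dispersion parameterization
(variance mu + mu^2/theta), the standard overdispersion model for UMI data.
Cluster structure enters through log-normal gene profiles perturbed per
cluster, batches through multiplicative per-gene effects (additive in log),
and doublets through cross-species transcript mixing as in a barnyard
experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CountMatrix, GroundTruth

logger = logging.getLogger(__name__)

#: Number of combined pseudo-clusters the disease simulator emulates
#: (two ages x 22 cell types).
N_PSEUDO_CLUSTERS = 44


@dataclass
class SimulationConfig:
    """Parameters of the multi-cluster UMI count simulator.

    Defaults emulate a Drop-seq cortex run at desk scale: a median library of
    ~2500 transcripts over 2000 genes across several biological replicates,
    ~3% doublets, and a handful of transcriptionally distinct cell types.
    """

    n_cells: int = 600
    n_genes: int = 2000
    n_clusters: int = 3
    cluster_proportions: np.ndarray | None = None
    batch_count: int = 3
    batch_effect_sd: float = 0.15
    doublet_rate: float = 0.03
    mito_gene_fraction: float = 0.02
    mean_library_size: float = 2500.0
    dispersion: float = 2.0
    de_gene_fraction: float = 0.1
    de_lfc_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_proportions is None:
            self.cluster_proportions = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_proportions = np.asarray(self.cluster_proportions, dtype=float)
        if abs(self.cluster_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if len(self.cluster_proportions) != self.n_clusters:
            raise ValueError("cluster_proportions length must equal n_clusters")
        if min(self.n_cells, self.n_genes, self.n_clusters, self.batch_count) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must lie in [0, 1]")
        if self.n_clusters > self.n_cells:
            raise ValueError("n_clusters cannot exceed n_cells")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def simulate_dge(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a genes x cells UMI matrix with planted clusters and batches.

    Per-cluster mean profiles are a shared log-normal base profile with a
    ``de_gene_fraction`` subset of genes perturbed by N(0, de_lfc_sd) on the
    log scale per cluster; counts are NB with per-gene dispersion; batches
    multiply gene means by exp(N(0, batch_effect_sd)); a ``doublet_rate``
    fraction of cells average two clusters' profiles.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G, C, K = cfg.n_genes, cfg.n_cells, cfg.n_clusters

    base_log = rng.normal(0.0, 1.5, size=G)
    cluster_log = np.tile(base_log, (K, 1))
    de_mask = np.zeros((K, G), dtype=bool)
    n_de = int(round(cfg.de_gene_fraction * G))
    for k in range(K):
        idx = rng.choice(G, size=n_de, replace=False)
        cluster_log[k, idx] += rng.normal(0.0, cfg.de_lfc_sd, size=n_de)
        de_mask[k, idx] = True
    cluster_profiles = np.exp(cluster_log)
    cluster_profiles /= cluster_profiles.sum(axis=1, keepdims=True)

    cell_labels = rng.choice(K, size=C, p=cfg.cluster_proportions)
    batch_labels = rng.integers(0, cfg.batch_count, size=C)
    doublet_flags = rng.random(C) < cfg.doublet_rate

    batch_factors = np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.batch_count, G)))
    lib = rng.lognormal(np.log(cfg.mean_library_size), 0.3, size=C)
    theta = np.full(G, cfg.dispersion)

    profiles_per_cell = cluster_profiles[cell_labels].copy()
    if doublet_flags.any():
        partner = rng.integers(0, K, size=int(doublet_flags.sum()))
        profiles_per_cell[doublet_flags] = 0.5 * (
            profiles_per_cell[doublet_flags] + cluster_profiles[partner]
        )

    mu = profiles_per_cell * batch_factors[batch_labels] * lib[:, None]  # cells x genes
    counts = _nb_sample(rng, mu, theta[None, :])
    counts = sp.csr_matrix(counts.T)  # genes x cells

    n_mito = int(round(cfg.mito_gene_fraction * G))
    mito = np.zeros(G, dtype=bool)
    mito[rng.choice(G, size=n_mito, replace=False)] = True

    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(G)],
            "symbol": [f"Gene{i}" for i in range(G)],
            "length": rng.integers(300, 20000, size=G),
            "mito": mito,
            "species": "mouse",
        }
    )
    cell_meta = pd.DataFrame(
        {
            "barcode": [f"CELL{i:05d}" for i in range(C)],
            "batch": [f"rep{b}" for b in batch_labels],
        }
    )
    truth = GroundTruth(
        cell_labels=cell_labels,
        batch_labels=batch_labels,
        doublet_flags=doublet_flags,
        extras={"cluster_profiles": cluster_profiles, "de_mask": de_mask},
    )
    return CountMatrix(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta), truth


def simulate_barnyard(
    n_cells: int,
    doublet_rate: float,
    spikein_fraction: float = 0.03,
    seed: int = 0,
    mean_total: float = 2000.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-barcode species-split transcript totals.

    Singlets draw >= 95% of transcripts from their own species; doublets mix
    the two species at a Uniform(0.25, 0.75) fraction so that they fail the
    90%-specificity rule.  ``spikein_fraction`` controls the share of
    spiked-in cells of the second species (default 3%, the usual barnyard
    spike-in concentration).
    """
    for name, frac in (("doublet_rate", doublet_rate), ("spikein_fraction", spikein_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    doublet = rng.random(n_cells) < doublet_rate
    species = rng.random(n_cells) < spikein_fraction  # True = species_b
    totals = np.maximum(rng.lognormal(np.log(mean_total), 0.4, size=n_cells).astype(int), 10)

    frac_b = np.where(species, 1.0, 0.0)
    contamination = rng.uniform(0.0, 0.05, size=n_cells)
    frac_b = np.abs(frac_b - contamination)
    frac_b[doublet] = rng.uniform(0.25, 0.75, size=int(doublet.sum()))

    counts_b = rng.binomial(totals, frac_b)
    table = pd.DataFrame(
        {
            "barcode": [f"BC{i:05d}" for i in range(n_cells)],
            "transcripts_species_a": totals - counts_b,
            "transcripts_species_b": counts_b,
        }
    )
    truth = GroundTruth(
        doublet_flags=doublet,
        extras={"species_b": species, "totals": totals},
    )
    return table, truth


def simulate_trajectory_dge(
    n_cells: int = 500,
    n_genes: int = 1000,
    seed: int = 0,
    mean_library_size: float = 2500.0,
    dispersion: float = 2.0,
    dynamic_fraction: float = 0.4,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate cells along a latent 1-D differentiation continuum.

    A latent pseudotime t ~ Uniform(0, 1) drives a ``dynamic_fraction``
    subset of genes through monotone (log-linear) or sigmoidal mean curves;
    the remainder are flat.  Counts are NB around the per-cell curves.
    """
    if n_cells < 50:
        raise ValueError("need at least 50 cells for a trajectory")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)

    base_log = rng.normal(0.0, 1.2, size=n_genes)
    n_dyn = int(round(dynamic_fraction * n_genes))
    kinds = np.zeros(n_genes, dtype="U8")
    kinds[:] = "flat"
    dyn_idx = rng.choice(n_genes, size=n_dyn, replace=False)
    half = n_dyn // 2
    mono_idx, sig_idx = dyn_idx[:half], dyn_idx[half:]
    kinds[mono_idx] = "monotone"
    kinds[sig_idx] = "sigmoid"

    log_mu = np.tile(base_log, (n_cells, 1))
    slope = rng.uniform(1.5, 3.0, size=len(mono_idx)) * rng.choice([-1, 1], size=len(mono_idx))
    log_mu[:, mono_idx] += slope[None, :] * t[:, None]
    center = rng.uniform(0.3, 0.7, size=len(sig_idx))
    amp = rng.uniform(1.5, 3.0, size=len(sig_idx)) * rng.choice([-1, 1], size=len(sig_idx))
    log_mu[:, sig_idx] += amp[None, :] / (1.0 + np.exp(-10.0 * (t[:, None] - center[None, :])))

    # Genes follow their own rate curves; one global scale sets the mean
    # library size so flat genes stay flat (no compositional coupling).
    rates = np.exp(log_mu)
    scale = mean_library_size / rates.sum(axis=1).mean()
    lib_factor = rng.lognormal(0.0, 0.3, size=n_cells)
    mu = rates * scale * lib_factor[:, None]
    counts = sp.csr_matrix(_nb_sample(rng, mu, np.full(n_genes, dispersion)[None, :]).T)

    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "symbol": [f"Gene{i}" for i in range(n_genes)],
            "length": rng.integers(300, 20000, size=n_genes),
            "mito": np.zeros(n_genes, dtype=bool),
            "species": "mouse",
        }
    )
    cell_meta = pd.DataFrame(
        {
            "barcode": [f"CELL{i:05d}" for i in range(n_cells)],
            "batch": "rep0",
        }
    )
    slope_sign = np.zeros(n_genes)
    slope_sign[mono_idx] = np.sign(slope)
    sigmoid_sign = np.zeros(n_genes)
    sigmoid_sign[sig_idx] = np.sign(amp)
    truth = GroundTruth(
        pseudotime=t,
        extras={"gene_kind": kinds, "slope_sign": slope_sign, "sigmoid_sign": sigmoid_sign},
    )
    return CountMatrix(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta), truth


def simulate_state_cluster(
    n_cells: int = 100,
    n_genes: int = 500,
    n_program_genes: int = 30,
    on_fraction: float = 0.4,
    program_lfc: float = 2.0,
    seed: int = 0,
    mean_library_size: float = 2500.0,
    dispersion: float = 2.0,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate one cell type carrying a bimodal within-cluster state program.

    All cells share one NB expression profile except for ``n_program_genes``
    program genes whose mean is multiplied by exp(program_lfc) in the "on"
    state (a cell-cycle-like program active in ``on_fraction`` of cells).
    Ground truth records the binary state label per cell and the program
    gene indices.
    """
    rng = np.random.default_rng(seed)
    base_log = rng.normal(0.0, 1.2, size=n_genes)
    # Plant the program in moderately detected genes, so the on/off split
    # lands in the intermediate detection range where such state programs
    # are observable through dropout patterns.
    rates = np.exp(base_log)
    mu0 = rates / rates.sum() * mean_library_size
    p_detect_off = 1.0 - (dispersion / (dispersion + mu0)) ** dispersion
    candidates = np.flatnonzero((p_detect_off > 0.1) & (p_detect_off < 0.55))
    if n_program_genes > len(candidates):
        raise ValueError("too few moderately expressed genes for the program")
    program = rng.choice(candidates, size=n_program_genes, replace=False)
    state = rng.random(n_cells) < on_fraction

    log_mu = np.tile(base_log, (n_cells, 1))
    log_mu[np.ix_(state, program)] += program_lfc
    profiles = np.exp(log_mu)
    profiles /= profiles.sum(axis=1, keepdims=True)
    lib = rng.lognormal(np.log(mean_library_size), 0.3, size=n_cells)
    counts = sp.csr_matrix(
        _nb_sample(rng, profiles * lib[:, None], np.full(n_genes, dispersion)[None, :]).T
    )
    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "symbol": [f"Gene{i}" for i in range(n_genes)],
            "length": rng.integers(300, 20000, size=n_genes),
            "mito": np.zeros(n_genes, dtype=bool),
            "species": "mouse",
        }
    )
    cell_meta = pd.DataFrame(
        {"barcode": [f"CELL{i:05d}" for i in range(n_cells)], "batch": "rep0"}
    )
    truth = GroundTruth(
        state_labels=state.astype(int), extras={"program_genes": program}
    )
    return CountMatrix(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta), truth


@dataclass
class DiseasePanel:
    """A disease gene panel with per-gene multi-label phenotype annotations."""

    disease: str
    genes: list[str]
    phenotypes: pd.DataFrame  # genes x phenotype indicator matrix
    profiles: pd.DataFrame | None = None  # genes x pseudo-cluster expression

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique within a panel")


DEFAULT_PHENOTYPES = (
    "microcephaly",
    "hydrocephaly",
    "axonal_tract_defects",
    "intellectual_disability",
)


def simulate_disease_panel(
    n_genes: int,
    n_subtypes: int,
    profiles: np.ndarray | None = None,
    association_strength: float = 0.0,
    noise_sd: float = 0.35,
    seed: int = 0,
    disease: str = "SYN",
) -> tuple[DiseasePanel, GroundTruth]:
    """Simulate a disease panel with planted expression subtypes.

    Each gene inherits one of ``n_subtypes`` template profiles across 44
    pseudo-clusters (two ages x 22 types) plus Gaussian noise.  Phenotype
    labels are drawn with subtype-dependent probabilities scaled by
    ``association_strength``; at 0 the labels are independent of subtype.
    """
    if n_subtypes < 2:
        raise ValueError("need at least 2 subtypes")
    if n_genes < 3 * n_subtypes:
        raise ValueError("need at least 3 genes per subtype")
    rng = np.random.default_rng(seed)
    generated_templates = profiles is None
    if profiles is None:
        # Cell-class-peaked templates: each subtype is elevated in its own
        # block of pseudo-clusters and depressed elsewhere, so that
        # different subtypes anticorrelate, as real cell-type-specific
        # disease genes do.
        profiles = np.full((n_subtypes, N_PSEUDO_CLUSTERS), 0.0)
        blocks = np.array_split(np.arange(N_PSEUDO_CLUSTERS), n_subtypes)
        amplitude = 1.5
        for s, block in enumerate(blocks):
            profiles[s, :] = -amplitude / max(n_subtypes - 1, 1)
            profiles[s, block] = amplitude
    profiles = np.asarray(profiles, dtype=float)
    n_clusters = profiles.shape[1]
    blocks = np.array_split(np.arange(n_clusters), n_subtypes)

    subtype_labels = np.repeat(np.arange(n_subtypes), n_genes // n_subtypes)
    subtype_labels = np.concatenate(
        [subtype_labels, rng.integers(0, n_subtypes, size=n_genes - len(subtype_labels))]
    )
    expr = profiles[subtype_labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_clusters))
    # Per-gene reciprocal depletion: each gene is most depleted in one
    # specific other cell class (cycling over the alternatives within a
    # subtype), mimicking e.g. neuronal genes being lowest in progenitors.
    # Applied only to generated templates; user templates pass through.
    if generated_templates and n_subtypes >= 2:
        counters = {s: 0 for s in range(n_subtypes)}
        depletion = 1.2
        for g, s in enumerate(subtype_labels):
            others = [r for r in range(n_subtypes) if r != s]
            anti = others[counters[s] % len(others)]
            counters[s] += 1
            expr[g, blocks[anti]] -= depletion

    phenos = list(DEFAULT_PHENOTYPES)
    base_p = 0.3
    preferred = np.arange(n_subtypes) % len(phenos)
    prob = np.full((n_genes, len(phenos)), base_p)
    hit = preferred[subtype_labels]
    prob[np.arange(n_genes), hit] = base_p + association_strength * (0.95 - base_p)
    annotations = (rng.random((n_genes, len(phenos))) < prob).astype(int)

    genes = [f"{disease}_{i:03d}" for i in range(n_genes)]
    panel = DiseasePanel(
        disease=disease,
        genes=genes,
        phenotypes=pd.DataFrame(annotations, index=genes, columns=phenos),
        profiles=pd.DataFrame(
            expr, index=genes, columns=[f"C{j:02d}" for j in range(n_clusters)]
        ),
    )
    truth = GroundTruth(subtype_labels=subtype_labels, extras={"templates": profiles})
    return panel, truth
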