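"""End-to-end orchestration: qc -> dimred -> cluster -> markers -> subcluster
-> trajectory -> compare -> disease, with a reproducibility manifest.

Every stage draws its randomness from a seed derived deterministically from
the global seed and the stage name, so disabling one stage never shifts
another stage's random stream.  Rerunning with an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, compare, dimred, disease, markers, qc, subcluster, trajectory
from .core import CountMatrix
from .io import read_count_matrix, write_count_matrix
from .synthetic import SimulationConfig, simulate_dge, simulate_disease_panel

logger = logging.getLogger(__name__)

STAGES = ("qc", "dimred", "cluster", "markers", "subcluster", "trajectory", "compare", "disease")

STAGE_DEPENDENCIES = {
    "dimred": ("qc",),
    "cluster": ("dimred",),
    "markers": ("qc", "cluster"),
    "subcluster": ("qc", "cluster"),
    "trajectory": ("dimred", "cluster"),
    "compare": ("qc", "cluster"),
    "disease": (),
}


@dataclass
class PipelineConfig:
    """All stage toggles and parameters, with conventional defaults."""

    outdir: str = "run"
    input_dir: str | None = None  # MTX trio; when None, simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple = STAGES
    seed: int = 0
    # qc
    min_genes: int = qc.MIN_GENES_PER_CELL
    max_mito: float = qc.MAX_MITO_FRACTION
    min_cells: int = qc.MIN_CELLS_PER_GENE
    min_transcripts: int = qc.MIN_TRANSCRIPTS_PER_GENE
    # dimred
    n_permutations: int = dimred.DEFAULT_N_PERMUTATIONS
    # cluster
    k_min: int = clustering.K_MIN
    k_max: int = clustering.K_MAX
    k_step: int = 1
    refine_iterations: int = clustering.REFINE_ITERATIONS
    outlier_threshold: float = clustering.OUTLIER_THRESHOLD
    min_novel: int = clustering.MIN_NOVEL_SIZE
    # subcluster
    subcluster_min_frac: float = subcluster.MIN_DETECTION_FRACTION
    subcluster_max_frac: float = subcluster.MAX_DETECTION_FRACTION
    subcluster_min_size: int = subcluster.MIN_SUBCLUSTER_SIZE
    # trajectory
    trajectory_min_abundance: float = 2.0
    trajectory_min_cells: int = 10
    loess_span: float = trajectory.DEFAULT_SPAN
    # compare
    min_rho: float = 0.4
    # disease
    cut_height: float = disease.DEFAULT_CUT_HEIGHT
    cut_height_asd: float = disease.ASD_CUT_HEIGHT
    n_mc: int = disease.DEFAULT_N_MC


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order and write a manifest.

    Raises if a requested stage's dependency stage is disabled, naming the
    missing upstream artifact.
    """
    cfg = config
    enabled = [s for s in STAGES if s in cfg.stages]
    for s in enabled:
        for dep in STAGE_DEPENDENCIES.get(s, ()):
            if dep not in enabled:
                raise ValueError(
                    f"stage '{s}' requires the output of disabled stage '{dep}' "
                    f"(missing artifact: {dep} stage outputs)"
                )

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": enabled,
        "parameters": {
            k: v for k, v in asdict(cfg).items()
            if k not in ("simulation", "outdir") and not isinstance(v, (dict,))
        },
        "inputs": {},
        "artifacts": {},
    }

    # ---- input ----
    if cfg.input_dir is not None:
        m = read_count_matrix(cfg.input_dir)
        for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
            manifest["inputs"][f] = _checksum(Path(cfg.input_dir) / f)
        truth = None
    else:
        sim_cfg = cfg.simulation
        sim_cfg.seed = stage_seed(cfg.seed, "simulate")
        m, truth = simulate_dge(sim_cfg)
        write_count_matrix(m, outdir / "simulated")
        manifest["inputs"]["simulation"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(sim_cfg).items()
        }

    artifacts: dict = {}

    # ---- qc ----
    if "qc" in enabled:
        filtered = qc.filter_genes(
            qc.filter_cells(m, min_genes=cfg.min_genes, max_mito=cfg.max_mito),
            min_cells=cfg.min_cells, min_transcripts=cfg.min_transcripts,
        )
        norm = qc.normalize_log(filtered)
        adjusted = qc.adjust_batches(norm, filtered.cell_meta["batch"].to_numpy())
        artifacts["qc"] = {"matrix": filtered, "normalized": norm, "adjusted": adjusted}
        pd.DataFrame(
            {
                "barcode": filtered.cell_meta["barcode"],
                "batch": filtered.cell_meta["batch"],
            }
        ).pipe(_write_tsv, outdir / "qc_cells.tsv")

    # ---- dimred ----
    if "dimred" in enabled:
        z, kept = dimred.zscore_genes(artifacts["qc"]["adjusted"])
        emb = dimred.select_significant_pcs(
            z, n_perm=cfg.n_permutations, seed=stage_seed(cfg.seed, "dimred")
        )
        artifacts["dimred"] = {"embedding": emb, "kept_genes": kept}
        coords = pd.DataFrame(
            emb.coordinates,
            columns=[f"PC{i+1}" for i in range(emb.coordinates.shape[1])],
        )
        coords.insert(0, "barcode", artifacts["qc"]["matrix"].cell_meta["barcode"].to_numpy())
        _write_tsv(coords, outdir / "embedding.tsv")

    # ---- cluster ----
    if "cluster" in enabled:
        emb = artifacts["dimred"]["embedding"]
        n = emb.coordinates.shape[0]
        k_max = min(cfg.k_max, n - 1)
        scan = clustering.scan_neighborhood_sizes(
            emb.coordinates, k_min=cfg.k_min, k_max=k_max, k_step=cfg.k_step,
            seed=stage_seed(cfg.seed, "cluster"),
        )
        refined = clustering.refine_assignments(
            scan.distance, scan.assignment, n_iter=cfg.refine_iterations,
            outlier_threshold=cfg.outlier_threshold, min_novel=cfg.min_novel,
        )
        artifacts["cluster"] = {"scan": scan, "assignment": refined}
        out = pd.DataFrame(
            {
                "barcode": artifacts["qc"]["matrix"].cell_meta["barcode"].to_numpy(),
                "cluster": refined.labels,
                "silhouette": refined.silhouettes,
                "flagged": refined.flags,
                "k_used": refined.k_used,
            }
        )
        _write_tsv(out, outdir / "clusters.tsv")
        _write_tsv(pd.DataFrame(scan.records), outdir / "k_scan.tsv")

    # ---- markers ----
    if "markers" in enabled:
        labels = artifacts["cluster"]["assignment"].labels
        gene_names = artifacts["qc"]["matrix"].gene_meta["symbol"].tolist()
        table = markers.rank_markers(artifacts["qc"]["normalized"], labels, gene_names)
        artifacts["markers"] = {"table": table}
        _write_tsv(table, outdir / "markers.tsv")

    # ---- subcluster ----
    if "subcluster" in enabled:
        labels = artifacts["cluster"]["assignment"].labels
        gene_names = artifacts["qc"]["matrix"].gene_meta["symbol"].tolist()
        norm = artifacts["qc"]["normalized"]
        rows = []
        results = {}
        for c in np.unique(labels):
            cells = labels == c
            if cells.sum() < 20:
                continue
            het = subcluster.heterogeneous_genes(
                norm[:, cells], gene_names,
                min_frac=cfg.subcluster_min_frac, max_frac=cfg.subcluster_max_frac,
            )
            if len(het) < 2:
                rows.append({"cluster": c, "n_subclusters": 0})
                continue
            res = subcluster.detect_subclusters(
                norm[:, cells], het, gene_names, cluster_id=c,
                min_size=cfg.subcluster_min_size,
            )
            results[c] = res
            rows.append(
                {"cluster": c,
                 "n_subclusters": 0 if res.labels is None else len(np.unique(res.labels))}
            )
        artifacts["subcluster"] = {"results": results}
        _write_tsv(pd.DataFrame(rows), outdir / "subclusters.tsv")

    # ---- trajectory ----
    if "trajectory" in enabled:
        emb = artifacts["dimred"]["embedding"]
        labels = artifacts["cluster"]["assignment"].labels
        sizes = pd.Series(labels).value_counts()
        if len(sizes) >= 2 and emb.coordinates.shape[0] >= 30:
            start_c, end_c = sizes.index[0], sizes.index[1]
            res = trajectory.fit_pseudotime(
                emb.coordinates, labels, start_c, end_c, span=cfg.loess_span
            )
            artifacts["trajectory"] = {"result": res}
            _write_tsv(
                pd.DataFrame(
                    {
                        "barcode": artifacts["qc"]["matrix"].cell_meta["barcode"].to_numpy(),
                        "pseudotime": res.pseudotime,
                        "order": np.argsort(res.order, kind="stable"),
                    }
                ),
                outdir / "pseudotime.tsv",
            )

    # ---- compare ----
    if "compare" in enabled:
        labels = artifacts["cluster"]["assignment"].labels
        gene_names = artifacts["qc"]["matrix"].gene_meta["symbol"].tolist()
        profiles = compare.collapse_cluster_profiles(
            artifacts["qc"]["normalized"], labels, gene_names, tag="self"
        )
        rho, links = compare.cross_correlate_types(
            profiles, profiles, list(profiles.index), min_rho=cfg.min_rho
        )
        artifacts["compare"] = {"profiles": profiles, "rho": rho, "links": links}
        profiles.reset_index(names="gene").pipe(_write_tsv, outdir / "cluster_profiles.tsv")
        _write_tsv(links, outdir / "correlation_links.tsv")
        if profiles.shape[1] >= 3:
            _, newick, _ = compare.cross_age_dendrogram(profiles)
            (outdir / "dendrogram.nwk").write_text(newick + "\n")

    # ---- disease ----
    if "disease" in enabled:
        panel, panel_truth = simulate_disease_panel(
            n_genes=48, n_subtypes=4, association_strength=0.8,
            seed=stage_seed(cfg.seed, "disease"),
        )
        cut = cfg.cut_height_asd if panel.disease == "ASD" else cfg.cut_height
        subtype = disease.subtype_disease_genes(panel.profiles, cut_height=cut)
        cat_map = disease.default_category_map(list(panel.profiles.columns))
        summary = disease.summarize_subtype_profiles(panel.profiles, subtype.subgroups, cat_map)
        table, p = disease.phenotype_association_test(
            subtype.subgroups, panel.phenotypes, n_mc=cfg.n_mc,
            seed=stage_seed(cfg.seed, "disease_mc"),
        )
        artifacts["disease"] = {
            "panel": panel, "truth": panel_truth, "subtype": subtype,
            "summary": summary, "contingency": table, "p_value": p,
        }
        summary.reset_index(names="subgroup").pipe(_write_tsv, outdir / "disease_summary.tsv")
        table.reset_index(names="subgroup").pipe(_write_tsv, outdir / "disease_contingency.tsv")
        (outdir / "disease_p_value.txt").write_text(f"{p:.6g}\n")

    for f in sorted(outdir.iterdir()):
        if f.is_file():
            manifest["artifacts"][f.name] = _checksum(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    run_pipeline.last_artifacts = artifacts  # introspection hook for tests/scripts
    return outdir
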