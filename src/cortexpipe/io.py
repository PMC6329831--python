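"""Standard-format I/O: MatrixMarket trios, GMT gene sets, Newick trees.

On-disk layout for a count matrix is the droplet-sequencing convention:
``matrix.mtx`` (genes x cells), ``genes.tsv`` (id, symbol, length, mito,
species), ``barcodes.tsv`` (barcode, batch, ...).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.cluster.hierarchy import ClusterNode, to_tree

from .core import CountMatrix


def write_count_matrix(m: CountMatrix, outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), m.counts.tocoo(), field="integer")
    m.gene_meta.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    m.cell_meta.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)


def read_count_matrix(indir: str | os.PathLike) -> CountMatrix:
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    gene_meta = pd.read_csv(indir / "genes.tsv", sep="\t")
    cell_meta = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    return CountMatrix(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta)


def write_gmt(gene_sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def linkage_to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage as a Newick string with branch lengths."""
    tree = to_tree(linkage_matrix)

    def build(node: ClusterNode, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.get_left(), node.dist)
        right = build(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
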