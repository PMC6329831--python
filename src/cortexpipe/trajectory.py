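"""Endpoint-constrained pseudotime via a principal curve, and loess gene curves.

A single curvilinear trajectory is fit through PC space by iterated
projection and local-linear smoothing, with two designated clusters
constrained as endpoints: the curve's extremities are anchored to the
endpoint-cluster medoids and pseudotime is oriented so the start cluster
maps near 0.  Pseudotime is the normalized arc length of each cell's
projection onto the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.5
CONVERGENCE_TOL = 1e-4
MAX_ITER = 50
GRID_SIZE = 100


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray  # in [0, 1] per cell
    order: np.ndarray  # argsort of pseudotime
    curve: np.ndarray  # control points in PC space (grid x dims)
    start_cluster: object
    end_cluster: object
    converged: bool
    n_iter: int


def select_trajectory_genes(
    abundance: np.ndarray,
    min_abundance: float = 2.0,
    min_cells: int = 10,
) -> np.ndarray:
    """Boolean mask of genes with abundance >= ``min_abundance`` in at least
    ``min_cells`` cells (abundance in per-cell-total-scaled units, TPM-like)."""
    abundance = np.asarray(abundance, dtype=float)
    mask = (abundance >= min_abundance).sum(axis=1) >= min_cells
    if not mask.any():
        raise ValueError("no genes pass the trajectory abundance filter")
    return mask


def counts_to_tpm_like(counts) -> np.ndarray:
    """Scale each cell's counts to transcripts-per-million of its total."""
    import scipy.sparse as sp

    if sp.issparse(counts):
        totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
        return counts.multiply(1e6 / np.maximum(totals, 1.0)[None, :]).toarray()
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    return counts * (1e6 / np.maximum(totals, 1.0))[None, :]


def _smooth_coordinates(t: np.ndarray, points: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    curve = np.empty((len(grid), points.shape[1]))
    for dim in range(points.shape[1]):
        curve[:, dim] = lowess(
            points[:, dim], t, frac=span, xvals=grid, it=0, return_sorted=False
        )
    return curve


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto the polyline; return (arc-length param, projected points)."""
    seg = np.diff(curve, axis=0)  # (m-1, d)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1] if cum[-1] > 0 else 1.0

    diffs = points[:, None, :] - curve[None, :-1, :]  # (n, m-1, d)
    seg_sq = np.maximum((seg**2).sum(axis=1), 1e-30)
    frac = np.clip(np.einsum("nmd,md->nm", diffs, seg) / seg_sq, 0.0, 1.0)
    proj = curve[None, :-1, :] + frac[:, :, None] * seg[None, :, :]
    dist_sq = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(dist_sq, axis=1)
    n = len(points)
    arc = cum[best] + frac[np.arange(n), best] * seg_len[best]
    return arc / total, proj[np.arange(n), best]


def fit_pseudotime(
    coords: np.ndarray,
    labels: np.ndarray,
    start_cluster,
    end_cluster,
    span: float = DEFAULT_SPAN,
    max_iter: int = MAX_ITER,
    tol: float = CONVERGENCE_TOL,
    grid_size: int = GRID_SIZE,
) -> PseudotimeResult:
    """Fit a principal curve through PC space with constrained endpoints."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = len(coords)
    if n < 30:
        raise ValueError("pseudotime fitting needs at least 30 cells")
    for c in (start_cluster, end_cluster):
        if c not in labels:
            raise ValueError(f"endpoint cluster {c!r} absent from labels")

    def medoid(cluster) -> np.ndarray:
        pts = coords[labels == cluster]
        d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        return pts[np.argmin(d.sum(axis=1))]

    start_medoid, end_medoid = medoid(start_cluster), medoid(end_cluster)

    # Endpoint constraint: initialize pseudotime along the axis joining the
    # endpoint-cluster medoids (falling back to PC1 if they coincide), so
    # the curve grows out of the constrained geometry; orientation is
    # re-checked after convergence.  Hard-clamping the curve extremities to
    # the medoids is avoided deliberately: it kinks the polyline and breaks
    # the exact straight-line limit.
    axis = end_medoid - start_medoid
    if np.linalg.norm(axis) < 1e-12:
        axis = np.zeros(coords.shape[1])
        axis[0] = 1.0
    t = (coords - start_medoid) @ axis
    if t[labels == start_cluster].mean() > t[labels == end_cluster].mean():
        t = -t
    t = (t - t.min()) / max(t.max() - t.min(), 1e-12)

    grid = np.linspace(0.0, 1.0, grid_size)
    prev_proj = None
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        curve = _smooth_coordinates(t, coords, grid, span)
        t_new, proj = _project_to_polyline(coords, curve)
        spread = t_new.max() - t_new.min()
        t = (t_new - t_new.min()) / max(spread, 1e-12)
        if prev_proj is not None:
            shift = float(np.linalg.norm(proj - prev_proj, axis=1).mean())
            if shift < tol:
                converged = True
                break
        prev_proj = proj
    if not converged:
        logger.warning("principal curve did not converge in %d iterations", max_iter)

    if t[labels == start_cluster].mean() > t[labels == end_cluster].mean():
        t = 1.0 - t
        curve = curve[::-1]
    return PseudotimeResult(
        pseudotime=t,
        order=np.argsort(t, kind="stable"),
        curve=curve,
        start_cluster=start_cluster,
        end_cluster=end_cluster,
        converged=converged,
        n_iter=it,
    )


def smooth_over_pseudotime(
    values: np.ndarray,
    pseudotime: np.ndarray,
    span: float = DEFAULT_SPAN,
    grid_size: int = GRID_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Loess-smoothed Z-scored expression over a fixed pseudotime grid.

    Local-linear regression with tricube weights of the Z-scored values on
    pseudotime, evaluated on ``grid_size`` equispaced points spanning the
    observed pseudotime range.  Returns ``(grid, smoothed)``.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    if len(values) < 20:
        raise ValueError("smoothing needs at least 20 cells")
    sd = values.std()
    z = (values - values.mean()) / sd if sd > 0 else values - values.mean()
    grid = np.linspace(pseudotime.min(), pseudotime.max(), grid_size)
    smoothed = lowess(z, pseudotime, frac=span, xvals=grid, it=0, return_sorted=False)
    return grid, smoothed
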