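"""Geometric morphometrics of six-corner facet shapes.

Generalised Procrustes analysis (translation, unit centroid size, rotation
and — because facets from left and right eyes are mirror images — optional
reflection) superimposes the landmark sets; principal components of the
aligned coordinates ordinate shape variation; Ward-linkage hierarchical
clustering groups facets, with the optimal cluster count chosen by the
relative between-cluster inertia gain; and Pearson chi-square tests ask
whether cluster composition depends on sex, strain or eye position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_core import logger

LM_COLUMNS = [f"lm{i}_{ax}" for i in range(1, 7) for ax in ("x", "y")]


def shapes_from_table(df: pd.DataFrame) -> np.ndarray:
    """(n, 6, 2) landmark array from a table with lm1_x … lm6_y columns."""
    return df[LM_COLUMNS].to_numpy(dtype=float).reshape(-1, 6, 2)


def _normalise(shape: np.ndarray) -> np.ndarray:
    centred = shape - shape.mean(axis=0)
    size = np.linalg.norm(centred)
    if size == 0:
        raise ValueError("degenerate shape: zero centroid size")
    return centred / size


def _optimal_rotation(
    shape: np.ndarray, target: np.ndarray, allow_reflection: bool
) -> np.ndarray:
    """Rotation (optionally improper) minimising ||shape @ R − target||."""
    u, _, vt = np.linalg.svd(shape.T @ target)
    R = u @ vt
    if not allow_reflection and np.linalg.det(R) < 0:
        u[:, -1] *= -1
        R = u @ vt
    return R


def procrustes_align(
    shapes: np.ndarray,
    allow_reflection: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalised Procrustes superimposition.

    Each shape is translated to zero centroid, scaled to unit centroid size
    and rotated (reflection allowed per shape when ``allow_reflection``) to
    the running consensus, iterating until the consensus moves less than
    ``tol``.  Returns (aligned shapes, consensus).
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 3 or shapes.shape[0] < 2:
        raise ValueError("need at least 2 shapes of consistent landmarks")
    aligned = np.stack([_normalise(s) for s in shapes])
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(len(aligned)):
            aligned[i] = aligned[i] @ _optimal_rotation(
                aligned[i], consensus, allow_reflection
            )
        new_consensus = _normalise(aligned.mean(axis=0))
        # fix the consensus orientation gauge to the first shape
        new_consensus = new_consensus @ _optimal_rotation(
            new_consensus, aligned[0], allow_reflection=False
        )
        if np.linalg.norm(new_consensus - consensus) < tol:
            consensus = new_consensus
            break
        consensus = new_consensus
    for i in range(len(aligned)):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus,
                                                    allow_reflection)
    return aligned, consensus


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = True
) -> float:
    """Full Procrustes distance between two landmark shapes."""
    x, y = _normalise(np.asarray(a, float)), _normalise(np.asarray(b, float))
    R = _optimal_rotation(x, y, allow_reflection)
    return float(np.linalg.norm(x @ R - y))


@dataclass
class ShapeSpace:
    """Aligned shapes with their principal-component ordination."""

    aligned: np.ndarray                  # (n, 6, 2)
    consensus: np.ndarray                # (6, 2)
    scores: np.ndarray                   # (n, k) PC scores
    variance_fraction: np.ndarray        # (k,) sums to 1
    components: np.ndarray               # (k, 12) loadings
    cluster: np.ndarray | None = None
    n_clusters: int | None = None


def shape_pca(aligned: np.ndarray, consensus: np.ndarray | None = None) -> ShapeSpace:
    """Principal components of the flattened aligned coordinates."""
    aligned = np.asarray(aligned, dtype=float)
    n = aligned.shape[0]
    if n < 3:
        raise ValueError("need at least 3 shapes for PCA")
    flat = aligned.reshape(n, -1)
    mean = flat.mean(axis=0)
    centred = flat - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = u * s
    if consensus is None:
        consensus = mean.reshape(6, 2)
    return ShapeSpace(
        aligned=aligned, consensus=consensus, scores=scores,
        variance_fraction=frac, components=vt,
    )


def cluster_shapes(
    space: ShapeSpace,
    n_clusters: int | str = "auto",
    max_clusters: int = 8,
) -> tuple[np.ndarray, int]:
    """Ward-linkage hierarchical clustering on the PC scores.

    ``n_clusters='auto'`` picks the cut maximising the relative
    between-cluster inertia gain (the largest drop in within-cluster inertia
    relative to the next drop); identical shapes yield a single cluster.
    Assignments are also stored on ``space``.
    """
    X = space.scores
    n = len(X)
    if n < 4:
        raise ValueError("need at least 4 shapes to cluster")
    total_inertia = float(((X - X.mean(axis=0)) ** 2).sum())
    if total_inertia < 1e-18:
        assign = np.ones(n, dtype=int)
        space.cluster, space.n_clusters = assign, 1
        return assign, 1
    Z = hierarchy.linkage(X, method="ward")
    kmax = min(max_clusters, n - 1)
    if isinstance(n_clusters, int):
        if n_clusters > n:
            raise ValueError("more clusters than shapes")
        assign = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        space.cluster, space.n_clusters = assign, int(assign.max())
        return assign, int(assign.max())

    def within(k: int) -> float:
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        w = 0.0
        for c in np.unique(lab):
            pts = X[lab == c]
            w += float(((pts - pts.mean(axis=0)) ** 2).sum())
        return w

    W = {k: within(k) for k in range(1, kmax + 2)}
    eps = 1e-12 * total_inertia
    best_k, best_ratio = 1, -math.inf
    for k in range(2, kmax + 1):
        gain_here = W[k - 1] - W[k]
        gain_next = max(W[k] - W[k + 1], eps)
        ratio = gain_here / gain_next
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    assign = hierarchy.fcluster(Z, t=best_k, criterion="maxclust")
    space.cluster, space.n_clusters = assign, int(assign.max())
    return assign, int(assign.max())


def composition_test(
    assignments: np.ndarray, factor: np.ndarray | pd.Series
) -> tuple[float, int, float]:
    """Pearson chi-square of the cluster × factor contingency table.

    Returns (chi-square, df, p) with df = (r−1)(c−1); raises on a zero
    expected count and warns when any expected count is below 5.
    """
    table = pd.crosstab(pd.Series(assignments, name="cluster"),
                        pd.Series(np.asarray(factor), name="factor"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 clusters and 2 factor levels")
    obs = table.to_numpy()
    expected = stats.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise ValueError("zero expected count in contingency table")
    if (expected < 5).any():
        warnings.warn("expected counts below 5; chi-square approximation is weak")
        logger.warning("composition_test: expected counts below 5")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)
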