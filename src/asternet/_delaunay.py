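"""Deterministic Delaunay edge extraction.

Qhull resolves cocircular point groups (e.g. the four corners of a square)
by an arbitrary internal choice. To make edge sets reproducible across runs
and platforms we apply a symbolic perturbation before triangulating: each
point is displaced by a fixed per-index pseudo-random offset of order
1e-9 times the point-cloud diameter. Reported edge lengths are always
computed from the *unperturbed* coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay

from .errors import DegenerateInputError

__all__ = ["delaunay_edges"]

_KNUTH = 2654435761  # multiplicative hash constant


def _symbolic_perturbation(points: np.ndarray) -> np.ndarray:
    n = len(points)
    idx = np.arange(n, dtype=np.uint64)
    hx = ((idx * _KNUTH) % (1 << 32)).astype(np.float64) / (1 << 32)
    hy = ((idx * _KNUTH * 40503 + 12345) % (1 << 32)).astype(np.float64) / (1 << 32)
    diameter = float(np.ptp(points, axis=0).max())
    if diameter == 0.0:
        raise DegenerateInputError("all points coincide")
    eps = 1e-9 * diameter
    return points + eps * (np.column_stack([hx, hy]) - 0.5)


def delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Return the unique Delaunay edges of a 2D point set.

    Parameters
    ----------
    points
        Array of shape (n, 2), n ≥ 3, not all collinear.

    Returns
    -------
    Array of shape (n_edges, 2) of vertex index pairs with i < j, sorted
    lexicographically.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2:
        raise DegenerateInputError("points must have shape (n, 2)")
    if len(points) < 3:
        raise DegenerateInputError(f"need ≥ 3 points, got {len(points)}")
    # collinearity check on the raw coordinates
    centred = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(points).max())) < 2:
        raise DegenerateInputError("all points are collinear")
    tri = Delaunay(_symbolic_perturbation(points))
    s = tri.simplices
    pairs = np.concatenate([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    pairs = np.sort(pairs, axis=1)
    edges = np.unique(pairs, axis=0)
    return edges.astype(np.intp)
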