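"""Shared test utilities: independent oracles and tiny scene builders."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

import asternet as an
from asternet.synthetic import GroundTruthNetwork, add_noise, render_aster_image

PX = 750.0 / 2048.0  # default detector-grid calibration, μm per pixel


def brute_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """O(n⁴) empty-circumcircle Delaunay oracle for small point sets."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    for i, j, k in combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = (
            (ax * ax + ay * ay) * (by - cy)
            + (bx * bx + by * by) * (cy - ay)
            + (cx * cx + cy * cy) * (ay - by)
        ) / d
        uy = (
            (ax * ax + ay * ay) * (cx - bx)
            + (bx * bx + by * by) * (ax - cx)
            + (cx * cx + cy * cy) * (bx - ax)
        ) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        empty = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if (pts[m, 0] - ux) ** 2 + (pts[m, 1] - uy) ** 2 < r2 * (1 - 1e-12):
                empty = False
                break
        if empty:
            for a, b in ((i, j), (j, k), (i, k)):
                edges.add((min(a, b), max(a, b)))
    return edges


def star_points(
    cx: float, cy: float, radius: float = 12.0, n_limbs: int = 6, phase: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Junction plus limb endpoints with centre-to-tip edges."""
    angles = phase + np.arange(n_limbs) * 2 * np.pi / n_limbs
    pts = np.vstack(
        [[cx, cy]]
        + [[cx + radius * np.cos(t), cy + radius * np.sin(t)] for t in angles]
    )
    edges = np.array([(0, i + 1) for i in range(n_limbs)])
    return pts, edges


def single_star_scene(seed: int = 3, noisy: bool = True):
    """A lone 6-limb aster on a 40 × 40 μm frame; returns (frame, centre)."""
    spec = an.AsterFieldSpec(
        field_width_um=40.0,
        field_height_um=40.0,
        lattice_constant_um=11.0,
        strand_count_min=1,
        strand_count_max=1,
        strand_offset_um=0.0,
        pixel_size_um=PX,
        seed=seed,
    )
    pts, edges = star_points(20.0, 20.0)
    truth = GroundTruthNetwork(pts, edges, 11.0)
    frame = render_aster_image(truth, spec)
    if noisy:
        frame = add_noise(frame, spec)
    return frame, np.array([20.0, 20.0])


def two_star_scene(seed: int = 4, noisy: bool = True):
    """Two asters 30 μm apart on a 70 × 40 μm frame; returns (frame, centres)."""
    spec = an.AsterFieldSpec(
        field_width_um=70.0,
        field_height_um=40.0,
        lattice_constant_um=11.0,
        strand_count_min=1,
        strand_count_max=1,
        strand_offset_um=0.0,
        pixel_size_um=PX,
        seed=seed,
    )
    p1, e1 = star_points(20.0, 20.0)
    p2, e2 = star_points(50.0, 20.0, phase=0.3)
    truth = GroundTruthNetwork(
        np.vstack([p1, p2]), np.vstack([e1, e2 + len(p1)]), 11.0
    )
    frame = render_aster_image(truth, spec)
    if noisy:
        frame = add_noise(frame, spec)
    return frame, np.array([[20.0, 20.0], [50.0, 20.0]])


def interior_mask(points: np.ndarray, width: float, height: float, margin: float):
    return (
        (points[:, 0] >= margin)
        & (points[:, 0] <= width - margin)
        & (points[:, 1] >= margin)
        & (points[:, 1] <= height - margin)
    )


def precision_recall(
    true_pos: np.ndarray,
    det_pos: np.ndarray,
    width: float,
    height: float,
    margin: float = 20.0,
    tol_um: float = 2.0,
) -> tuple[float, float]:
    """Match detections to truth within ``tol_um``, evaluated on the frame
    interior (detections or true vertices within ``margin`` of the border
    are excluded from their own side, but may still serve as matches)."""
    ti = true_pos[interior_mask(true_pos, width, height, margin)]
    di = det_pos[interior_mask(det_pos, width, height, margin)]
    if len(di) == 0 or len(ti) == 0:
        return 0.0, 0.0
    precision = (cKDTree(true_pos).query(di)[0] <= tol_um).mean()
    recall = (cKDTree(det_pos).query(ti)[0] <= tol_um).mean()
    return float(precision), float(recall)
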