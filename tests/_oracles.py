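"""Independent brute-force oracles used by the tests.

Everything here is deliberately written against the definitions, not the
package internals: full distance-matrix DBSCAN closure, scalar distance
formulas, per-pixel metric loops. Shared FIFO/label-on-discovery tie-break
convention matches the package's documented determinism contract, but the
mechanisms (no spatial index, no hulls, no skipping) are independent.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def nd_scalar(p, q, dims, w1=2.0, w2=2.0, w3=1.0, w4=1.0, w5=1.0) -> float:
    """Normalized color+spatial distance, written out long-hand."""
    omega, h = dims
    color = (
        w3 * (p[2] - q[2]) ** 2 + w4 * (p[3] - q[3]) ** 2 + w5 * (p[4] - q[4]) ** 2
    ) / (3 * 255**2)
    spatial = ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2) / (omega**2 + h**2)
    return math.sqrt(color / w1 + spatial / w2)


def distance_matrix(pts: np.ndarray, metric: str, dims=None) -> np.ndarray:
    pts = np.asarray(pts, float)
    if metric == "euclidean":
        d = pts[:, None, :2] - pts[None, :, :2]
        return np.sqrt((d**2).sum(-1))
    if metric == "manhattan":
        d = pts[:, None, :2] - pts[None, :, :2]
        return np.abs(d).sum(-1)
    if metric == "nd":
        omega, h = dims
        dc = pts[:, None, 2:5] - pts[None, :, 2:5]
        ds = pts[:, None, :2] - pts[None, :, :2]
        return np.sqrt(
            (dc**2).sum(-1) / (3 * 255**2) / 2.0 + (ds**2).sum(-1) / (omega**2 + h**2) / 2.0
        )
    raise ValueError(metric)


def brute_dbscan(pts: np.ndarray, eps: float, min_pts: int, metric="euclidean", dims=None) -> np.ndarray:
    """Reachability-closure DBSCAN over the full distance matrix.

    Neighborhood excludes the query point; seeds scan in input order;
    expansion FIFO with label-on-discovery (border ties go to the first
    cluster that reaches them).
    """
    n = len(pts)
    d = distance_matrix(pts, metric, dims)
    adj = (d <= eps) & ~np.eye(n, dtype=bool)
    core = adj.sum(1) >= min_pts
    labels = np.zeros(n, int)
    cid = 0
    for s in range(n):
        if labels[s] or not core[s]:
            continue
        cid += 1
        labels[s] = cid
        queue = deque([s])
        while queue:
            p = queue.popleft()
            if not core[p]:
                continue
            for j in np.nonzero(adj[p])[0]:
                if not labels[j]:
                    labels[j] = cid
                    queue.append(int(j))
    labels[labels == 0] = -1
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Identical clusterings up to a bijective relabeling; noise matches exactly."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or ((a == -1) != (b == -1)).any():
        return False
    fwd: dict = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if fwd.setdefault(int(x), int(y)) != y:
            return False
    return len(set(fwd.values())) == len(fwd)


def random_binary_points(rng: np.random.Generator, lo=20, hi=50, dmin=0.2, dmax=0.7) -> np.ndarray:
    """Foreground pixel coordinates of a random binary image."""
    w, h = rng.integers(lo, hi + 1, 2)
    dens = rng.uniform(dmin, dmax)
    grid = rng.random((h, w)) < dens
    ys, xs = np.nonzero(grid)
    return np.column_stack([xs, ys]).astype(np.int32)


def random_patchwork_image(rng: np.random.Generator, w=32, h=32, n_rect=4) -> np.ndarray:
    """Piecewise-flat color image: base color plus random rectangles."""
    img = np.zeros((h, w, 3), np.uint8)
    img[:] = rng.integers(0, 256, 3)
    for _ in range(n_rect):
        x0, y0 = rng.integers(0, w - 8, 2)
        dw, dh = rng.integers(6, 16, 2)
        img[y0 : y0 + dh, x0 : x0 + dw] = rng.integers(0, 256, 3)
    return img


def image_points(img: np.ndarray) -> np.ndarray:
    h, w = img.shape[:2]
    ys, xs = np.mgrid[0:h, 0:w]
    return np.column_stack([xs.ravel(), ys.ravel(), img.reshape(-1, 3)]).astype(np.int32)
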