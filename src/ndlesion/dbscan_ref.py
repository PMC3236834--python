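"""Reference DBSCAN with pluggable pixel metrics.

This is the correctness oracle for the boundary-accelerated variant and
the "safe mode" for ND clustering. Semantics follow the classic algorithm
with two conventions fixed package-wide:

* the ε-neighborhood of a query point EXCLUDES the point itself, and a
  point is core iff that neighborhood holds at least MinPts points;
* the neighborhood ball is closed (distance <= ε).

Determinism: seeds are scanned in input order (row-major for points coming
from images), expansion is FIFO, and neighbor lists are returned in
ascending input order, so labels are reproducible bit-for-bit.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .distances import (
    NDWeights,
    euclidean_to_many,
    manhattan_to_many,
    nd_to_many,
    spatial_reach,
)

#: Label assigned to points belonging to no cluster.
NOISE = -1

Metric = Literal["euclidean", "manhattan", "nd"]


@dataclass(frozen=True)
class ClusterParams:
    """ε, MinPts and the distance mode of a clustering run."""

    eps: float
    min_pts: int
    metric: Metric = "euclidean"
    weights: NDWeights = field(default_factory=NDWeights)
    image_size: tuple[int, int] | None = None  # (ω, h); required scale for ND

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.metric not in ("euclidean", "manhattan", "nd"):
            raise ValueError(f"unknown metric {self.metric!r}")


class PointIndex:
    """Uniform spatial grid for fixed-radius neighbor queries.

    Cell size equals the spatial reach of ε (ε itself for the spatial
    metrics, the projected bound for ND), so all neighbors of a point lie
    in its 3×3 cell block.
    """

    def __init__(self, points: np.ndarray, params: ClusterParams):
        pts = np.asarray(points)
        if pts.ndim != 2 or pts.shape[1] < 2:
            raise ValueError("points must be (n, >=2)")
        if params.metric == "nd" and pts.shape[1] < 5:
            raise ValueError("ND metric needs (x, y, r, g, b) points")
        self.points = pts
        self.params = params
        if params.metric == "nd":
            if params.image_size is not None:
                self.dims = params.image_size
            else:
                self.dims = (int(pts[:, 0].max()) + 1, int(pts[:, 1].max()) + 1)
            self.reach = spatial_reach(params.eps, self.dims, params.weights)
        else:
            self.dims = params.image_size
            self.reach = params.eps
        cell = max(self.reach, 1e-9)
        cx = np.floor(pts[:, 0] / cell).astype(np.int64)
        cy = np.floor(pts[:, 1] / cell).astype(np.int64)
        self._cells: dict[tuple[int, int], np.ndarray] = {}
        order = np.lexsort((cx, cy))
        keys = np.column_stack([cx[order], cy[order]])
        if len(order):
            splits = np.flatnonzero(np.any(np.diff(keys, axis=0) != 0, axis=1)) + 1
            for chunk in np.split(order, splits):
                self._cells[(int(cx[chunk[0]]), int(cy[chunk[0]]))] = np.sort(chunk)
        self._cell_of = (cx, cy)

    def _candidates(self, i: int) -> np.ndarray:
        cx, cy = self._cell_of[0][i], self._cell_of[1][i]
        blocks = [
            self._cells[(x, y)]
            for x in (cx - 1, cx, cx + 1)
            for y in (cy - 1, cy, cy + 1)
            if (x, y) in self._cells
        ]
        return np.sort(np.concatenate(blocks)) if blocks else np.empty(0, np.int64)

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of all points within ε of point i, excluding i; ascending."""
        cand = self._candidates(i)
        p = self.points[i]
        q = self.points[cand]
        m = self.params.metric
        if m == "nd":
            d = nd_to_many(p, q, self.dims, self.params.weights)
        elif m == "euclidean":
            d = euclidean_to_many(p, q)
        else:
            d = manhattan_to_many(p, q)
        hit = cand[(d <= self.params.eps) & (cand != i)]
        return hit


def region_query(i: int, index: PointIndex) -> np.ndarray:
    """ε-neighborhood NEps of point ``i`` (query point excluded)."""
    return index.neighbors(i)


def dbscan(points: np.ndarray, params: ClusterParams) -> np.ndarray:
    """Cluster points; returns labels 1..K, NOISE (-1) for outliers."""
    est = ReferenceDBSCAN(
        eps=params.eps,
        min_pts=params.min_pts,
        metric=params.metric,
        weights=params.weights,
        image_size=params.image_size,
    )
    return est.fit(points).labels_


def core_status(i: int, index: PointIndex) -> str:
    """Classify point i as 'core', 'border' or 'noise'."""
    neigh = index.neighbors(i)
    if len(neigh) >= index.params.min_pts:
        return "core"
    for j in neigh:  # i is within ε of j by symmetry of all metrics
        if len(index.neighbors(int(j))) >= index.params.min_pts:
            return "border"
    return "noise"


class ReferenceDBSCAN(BaseEstimator, ClusterMixin):
    """Density-based clustering of image pixels.

    Parameters
    ----------
    eps : neighborhood radius in the units of the chosen metric
        (pixels for euclidean/manhattan, a unitless value < 1 for ND).
    min_pts : minimum neighbor count (query point excluded) for a core point.
    metric : 'euclidean', 'manhattan' (spatial only) or 'nd' (color+spatial).
    weights : ND weight set; ignored by the spatial metrics.
    image_size : (ω, h) normalization scale for ND; inferred from the data
        extent when omitted.

    Attributes
    ----------
    labels_ : ndarray of cluster ids 1..K, or -1 for noise.
    core_sample_mask_ : boolean ndarray marking core points.
    n_clusters_ : number of clusters found.
    """

    def __init__(
        self,
        eps: float = 1.5,
        min_pts: int = 5,
        metric: Metric = "euclidean",
        weights: NDWeights | None = None,
        image_size: tuple[int, int] | None = None,
    ):
        self.eps = eps
        self.min_pts = min_pts
        self.metric = metric
        self.weights = weights
        self.image_size = image_size

    def _params(self) -> ClusterParams:
        return ClusterParams(
            eps=self.eps,
            min_pts=self.min_pts,
            metric=self.metric,
            weights=self.weights or NDWeights(),
            image_size=self.image_size,
        )

    def fit(self, X, y=None):
        pts = np.asarray(X)
        if pts.ndim != 2 or len(pts) < 1:
            raise ValueError("need a non-empty (n, d) point array")
        params = self._params()
        index = PointIndex(pts, params)
        n = len(pts)
        labels = np.zeros(n, np.int32)  # 0 = unlabeled
        core = np.zeros(n, bool)
        cid = 0
        for seed in range(n):
            if labels[seed]:
                continue
            neigh = index.neighbors(seed)
            if len(neigh) < params.min_pts:
                continue  # not core; may become a border member later
            cid += 1
            core[seed] = True
            labels[seed] = cid
            queue = deque()
            for j in neigh:
                if not labels[j]:
                    labels[j] = cid
                    queue.append(int(j))
            while queue:
                q = queue.popleft()
                qn = index.neighbors(q)
                if len(qn) < params.min_pts:
                    continue
                core[q] = True
                for j in qn:
                    if not labels[j]:
                        labels[j] = cid
                        queue.append(int(j))
        labels[labels == 0] = NOISE
        self.labels_ = labels
        self.core_sample_mask_ = core
        self.n_clusters_ = cid
        self._index = index
        return self
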