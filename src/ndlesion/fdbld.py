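"""Boundary-accelerated density-based clustering (FDBLD).

DBSCAN fires one region query per point. FDBLD tracks each growing
cluster's boundary Γ — the union of convex hulls of the ε-neighborhoods
discovered so far — and skips the queries of members lying deeper than an
ε-width inner band below Γ: such a member's whole neighborhood provably
lies inside the already-covered region, so its query cannot change the
cluster.

Two modes share this machinery:

* spatial/binary mode (euclidean or manhattan metric on thresholded
  foreground pixels): hull containment implies direct density
  reachability, so the result provably equals reference DBSCAN;
* ND mode (joint color+spatial metric on all pixels): hulls live in the
  2-D spatial projection of a 5-D metric, so the band is widened to the
  spatial reach of ε and membership still accrues only from fired
  queries. Agreement with DBSCAN(ND) is measured, not assumed; with
  ``skip=False`` the two are identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import geometry
from .dbscan_ref import NOISE, ClusterParams, Metric, PointIndex
from .distances import NDWeights, spatial_reach
from .geometry import PolygonSet


@dataclass
class QueryStats:
    """Bookkeeping of the skip mechanism."""

    fired: int = 0
    skipped: int = 0
    total_points: int = 0

    @property
    def savings(self) -> float:
        """Fraction of points whose query was never fired."""
        return 1.0 - self.fired / self.total_points if self.total_points else 0.0


@dataclass
class Cluster:
    """A grown cluster: members plus its boundary polygon set Γ."""

    id: int
    members: list[int] = field(default_factory=list)
    gamma: PolygonSet = field(default_factory=PolygonSet)
    #: False once an inflated degenerate hull entered Γ: the inflation margin
    #: may cover pixels that are not members, so the skip test is no longer
    #: provably sound and queries are fired unconditionally for this cluster.
    skip_sound: bool = True


def band_width(params: ClusterParams, dims: tuple[int, int] | None) -> float:
    """Width of the leading-point inner band, in pixel units.

    ε itself for the spatial metrics; for ND the conservative spatial
    projection of ε (any ND-neighbor lies within this many pixels).
    """
    if params.metric == "nd":
        if dims is None:
            raise ValueError("ND band width needs image dimensions")
        return spatial_reach(params.eps, dims, params.weights)
    return params.eps


def is_leading(p_xy, cluster: Cluster, band: float) -> bool:
    """True iff the member can still alter the cluster boundary.

    Members lie inside Γ by construction (every hull covered its newly
    labeled points when it was unioned in), so a member farther than the
    band width from every ring of Γ has its entire neighborhood inside Γ
    and its query is skippable.
    """
    if cluster.gamma.is_empty:
        return True
    return geometry.boundary_distance(cluster.gamma, p_xy) <= band


def primitive_cluster(
    seed: int, index: PointIndex, inflate: float
) -> tuple[np.ndarray, "geometry.Polygon"] | None:
    """Members and hull of the primitive cluster around a core point.

    Returns None when the seed is not core (< MinPts neighbors).
    """
    neigh = index.neighbors(seed)
    if len(neigh) < index.params.min_pts:
        return None
    members = np.concatenate([[seed], neigh])
    hull, degenerate = geometry.convex_hull_ex(index.points[members, :2], inflate=inflate)
    return members, hull, degenerate


class FDBLD(BaseEstimator, ClusterMixin):
    """Fast density-based lesion detection clustering.

    Same parameters and fitted labels as :class:`ReferenceDBSCAN`, plus:

    skip : bool, default True
        Enable the leading-point query-skip mechanism. With False the
        algorithm degenerates to exact DBSCAN (every member queried).

    Attributes
    ----------
    labels_ : cluster ids 1..K or -1 (noise), aligned with the input rows.
    clusters_ : list of :class:`Cluster` with boundary polygon sets.
    query_stats_ : :class:`QueryStats` for the run.
    """

    def __init__(
        self,
        eps: float = 1.5,
        min_pts: int = 5,
        metric: Metric = "euclidean",
        weights: NDWeights | None = None,
        image_size: tuple[int, int] | None = None,
        skip: bool = True,
    ):
        self.eps = eps
        self.min_pts = min_pts
        self.metric = metric
        self.weights = weights
        self.image_size = image_size
        self.skip = skip

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
        band = band_width(params, index.dims)
        inflate = max(band / 4.0, 1e-6)

        n = len(pts)
        labels = np.zeros(n, np.int32)
        queried = np.zeros(n, bool)
        stats = QueryStats(total_points=n)
        clusters: list[Cluster] = []

        for seed in range(n):
            if labels[seed]:
                continue
            self._expand(seed, index, params, band, inflate, labels, queried, stats, clusters)

        labels[labels == 0] = NOISE
        self.labels_ = labels
        self.clusters_ = clusters
        self.query_stats_ = stats
        self.n_clusters_ = len(clusters)
        self._index = index
        return self

    def _expand(self, seed, index, params, band, inflate, labels, queried, stats, clusters) -> bool:
        stats.fired += 1
        queried[seed] = True
        pc = primitive_cluster(seed, index, inflate)
        if pc is None:
            return False
        members, hull, degenerate = pc
        cluster = Cluster(id=len(clusters) + 1)
        clusters.append(cluster)
        cluster.gamma = geometry.union_into(cluster.gamma, hull)
        if degenerate:
            cluster.skip_sound = False
        # LIFO pending list: depth-first discovery lets Γ overtake backlogged
        # members, so their queries become provably redundant and are skipped.
        # A FIFO wavefront would pop every member while it is still on the Γ
        # frontier and the skip test could never engage. Membership is
        # order-independent (clusters are reachability closures), so only the
        # amount of skipping changes.
        stack: list[int] = []
        for j in members:
            j = int(j)
            if not labels[j]:
                labels[j] = cluster.id
                cluster.members.append(j)
                if j != seed:
                    stack.append(j)
        while stack:
            p = stack.pop()
            if queried[p]:
                continue
            if (
                self.skip
                and cluster.skip_sound
                and not is_leading(index.points[p, :2], cluster, band)
            ):
                # Γ only grows, so a skipped interior member stays interior.
                stats.skipped += 1
                continue
            stats.fired += 1
            queried[p] = True
            neigh = index.neighbors(p)
            if len(neigh) < params.min_pts:
                continue
            new_members = np.concatenate([[p], neigh])
            hull, degenerate = geometry.convex_hull_ex(
                index.points[new_members, :2], inflate=inflate
            )
            cluster.gamma = geometry.union_into(cluster.gamma, hull)
            if degenerate:
                cluster.skip_sound = False
            for j in neigh:
                j = int(j)
                if not labels[j]:
                    labels[j] = cluster.id
                    cluster.members.append(j)
                    stack.append(j)
        return True


def fdbld_cluster(
    points: np.ndarray, params: ClusterParams, skip: bool = True
) -> tuple[np.ndarray, list[Cluster], QueryStats]:
    """Functional wrapper: labels, clusters with boundaries, query stats."""
    est = FDBLD(
        eps=params.eps,
        min_pts=params.min_pts,
        metric=params.metric,
        weights=params.weights,
        image_size=params.image_size,
        skip=skip,
    )
    est.fit(points)
    return est.labels_, est.clusters_, est.query_stats_
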