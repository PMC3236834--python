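"""2-D geometry for boundary-based clustering.

Cluster boundaries (Γ) are sets of simple polygons built by repeatedly
unioning convex hulls of ε-neighborhoods. shapely provides the polygon
primitives; this module fixes the conventions the clustering relies on:
degenerate hulls are inflated so containment stays meaningful, and Γ is
kept as the *exact* union of the hulls, holes included — donut-like
clusters need interior rings, and the leading-point band must hug them,
or queries near an uncovered hole would be skipped unsoundly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union


@dataclass
class PolygonSet:
    """One or more simple polygons (holes allowed) delimiting a region (Γ)."""

    polys: list[Polygon] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.polys) == 0

    @property
    def area(self) -> float:
        return float(sum(p.area for p in self.polys))

    def wkt(self) -> str:
        if not self.polys:
            return "GEOMETRYCOLLECTION EMPTY"
        if len(self.polys) == 1:
            return self.polys[0].wkt
        return shapely.MultiPolygon(self.polys).wkt

    def vertex_rows(self) -> list[tuple[int, float, float]]:
        """(shell index, x, y) rows for CSV export (exterior rings only)."""
        rows = []
        for i, p in enumerate(self.polys):
            for x, y in p.exterior.coords[:-1]:
                rows.append((i, float(x), float(y)))
        return rows


def _ccw(poly: Polygon) -> Polygon:
    if not shapely.is_ccw(shapely.get_exterior_ring(poly)):
        poly = shapely.reverse(poly)
    return poly


def convex_hull(points: Sequence[Sequence[float]], inflate: float = 0.25) -> Polygon:
    """Convex hull of 2-D points as a CCW simple polygon.

    Degenerate inputs (single point, two points, collinear sets) produce a
    thin rectangle of half-width ``inflate`` around the point/segment so
    that every input point lies inside or on the result and band tests
    stay defined.
    """
    return convex_hull_ex(points, inflate)[0]


def convex_hull_ex(
    points: Sequence[Sequence[float]], inflate: float = 0.25
) -> tuple[Polygon, bool]:
    """Like :func:`convex_hull` but also reports whether inflation was needed."""
    pts = np.asarray(points, np.float64)
    if pts.ndim != 2:
        pts = np.asarray([(p[0], p[1]) for p in points], np.float64)
    if len(pts) == 0:
        raise ValueError("convex hull of empty point set")
    hull = shapely.convex_hull(shapely.multipoints(pts[:, :2]))
    degenerate = hull.geom_type != "Polygon"  # point or line string
    if degenerate:
        hull = hull.buffer(max(inflate, 1e-9), cap_style="square", join_style="mitre")
    return _ccw(hull), degenerate


def _parts(geom) -> list[Polygon]:
    """Polygon parts of a (multi)polygon, holes preserved."""
    if geom.is_empty:
        return []
    parts = shapely.get_parts(geom) if geom.geom_type == "MultiPolygon" else [geom]
    return [_ccw(p) for p in parts if p.geom_type == "Polygon"]


def union_into(gamma: PolygonSet, hull: Polygon) -> PolygonSet:
    """Union a new primitive-cluster hull into the boundary Γ.

    The covered region is exactly region(Γ) ∪ region(hull) and can only
    grow: overlapping shells merge, a disjoint hull is appended as a new
    shell. Holes of ring-like (donut) unions are preserved — the covered
    region must never exceed the union of neighborhood hulls, otherwise
    points near an uncovered hole would wrongly count as deep interior
    and their queries could be skipped unsoundly.
    """
    if gamma.is_empty:
        return PolygonSet([_ccw(hull)])
    if len(gamma.polys) == 1:
        merged = gamma.polys[0].union(hull)
    else:
        merged = unary_union(gamma.polys + [hull])
    return PolygonSet(_parts(merged))


def contains(gamma: PolygonSet, p: Sequence[float]) -> bool:
    """True iff the point lies inside or on the boundary of any shell."""
    pt = Point(p[0], p[1])
    return any(poly.covers(pt) for poly in gamma.polys)


def boundary_distance(gamma: PolygonSet, p: Sequence[float]) -> float:
    """Euclidean distance from a point to the nearest ring of Γ (0 on an edge)."""
    if gamma.is_empty:
        raise ValueError("boundary distance of empty polygon set")
    pt = Point(p[0], p[1])
    d = min(pt.distance(poly.exterior) for poly in gamma.polys)
    interior = min(
        (pt.distance(ring) for poly in gamma.polys for ring in poly.interiors),
        default=np.inf,
    )
    return float(min(d, interior))


def polygons_to_csv(gamma: PolygonSet, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["shell", "x", "y"])
        wr.writerows(gamma.vertex_rows())
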