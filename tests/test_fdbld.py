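import numpy as np
import pytest
from shapely.geometry import Point

from ndlesion.dbscan_ref import NOISE, ClusterParams, PointIndex, dbscan
from ndlesion.fdbld import FDBLD, band_width, fdbld_cluster, is_leading, primitive_cluster
from ndlesion.geometry import boundary_distance, contains

from _oracles import brute_dbscan, image_points, random_binary_points, random_patchwork_image, same_partition


def solid_square(side, x0=0, y0=0):
    return np.array(
        [(x0 + dx, y0 + dy) for dy in range(side) for dx in range(side)], np.int32
    )


def ring(r_out=9, r_in=6, c=12):
    pts = []
    for y in range(2 * c):
        for x in range(2 * c):
            rr = np.hypot(x - c, y - c)
            if r_in <= rr <= r_out:
                pts.append((x, y))
    return np.array(pts, np.int32)


class TestPrimitiveCluster:
    def test_dense_neighborhood_forms_pc(self):
        pts = solid_square(3)
        idx = PointIndex(pts, ClusterParams(eps=1.5, min_pts=5))
        pc = primitive_cluster(4, idx, inflate=0.4)
        assert pc is not None
        members, hull, degenerate = pc
        assert len(members) == 9  # core + 8 neighbors
        assert not degenerate
        for m in members:
            assert hull.covers(Point(*map(float, pts[m])))

    def test_isolated_point_returns_none(self):
        pts = np.array([(0, 0), (40, 40)], np.int32)
        idx = PointIndex(pts, ClusterParams(eps=1.5, min_pts=5))
        assert primitive_cluster(0, idx, inflate=0.4) is None

    def test_hull_contains_members_on_random_neighborhoods(self, rng):
        for _ in range(20):
            pts = random_binary_points(rng, 15, 25)
            idx = PointIndex(pts, ClusterParams(eps=2.5, min_pts=4))
            i = int(rng.integers(len(pts)))
            pc = primitive_cluster(i, idx, inflate=0.6)
            if pc is None:
                continue
            members, hull, _ = pc
            for m in members:
                assert hull.covers(Point(*map(float, pts[m])))


class TestExpandAndCluster:
    def test_block_matches_dbscan(self):
        pts = solid_square(3)
        params = ClusterParams(eps=1.5, min_pts=5)
        labels, clusters, _ = fdbld_cluster(pts, params)
        assert same_partition(labels, dbscan(pts, params))
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == list(range(9))

    def test_noncore_seed_no_state_change(self):
        pts = np.array([(0, 0), (1, 0), (30, 30)], np.int32)
        labels, clusters, stats = fdbld_cluster(pts, ClusterParams(eps=1.5, min_pts=5))
        assert (labels == NOISE).all()
        assert clusters == []

    def test_donut_cluster_matches_dbscan_and_keeps_hole(self):
        pts = ring()
        params = ClusterParams(eps=1.5, min_pts=4)
        labels, clusters, _ = fdbld_cluster(pts, params)
        assert same_partition(labels, dbscan(pts, params))
        assert len(clusters) == 1
        gamma = clusters[0].gamma
        assert len(gamma.polys) >= 1
        assert not contains(gamma, (12.0, 12.0))  # hole is not covered

    def test_all_noise_scatter(self):
        pts = np.array([(0, 0), (15, 15), (30, 0)], np.int32)
        labels, clusters, stats = fdbld_cluster(pts, ClusterParams(eps=2.0, min_pts=3))
        assert (labels == NOISE).all() and not clusters
        assert stats.fired == 3  # one failed seed query each


class TestLeadingPoints:
    def test_deep_interior_not_leading(self):
        pts = solid_square(21)
        params = ClusterParams(eps=1.5, min_pts=5)
        est = FDBLD(eps=1.5, min_pts=5).fit(pts)
        cl = est.clusters_[0]
        band = band_width(params, None)
        center = pts[len(pts) // 2]
        assert boundary_distance(cl.gamma, center[:2]) > band
        assert not is_leading(center[:2], cl, band)

    def test_gamma_edge_point_leading(self):
        est = FDBLD(eps=1.5, min_pts=5).fit(solid_square(9))
        cl = est.clusters_[0]
        edge_xy = np.asarray(cl.gamma.polys[0].exterior.coords[0])
        assert is_leading(edge_xy, cl, band=1.5)

    def test_skipped_neighborhoods_provably_interior(self, rng):
        """Fire the skipped queries post-hoc: all neighbors must already be
        members of the same cluster (the skip changed nothing)."""
        for _ in range(10):
            side = int(rng.integers(10, 18))
            pts = solid_square(side)
            params = ClusterParams(eps=1.5, min_pts=5)
            est = FDBLD(eps=1.5, min_pts=5).fit(pts)
            idx = PointIndex(pts, params)
            assert est.query_stats_.skipped > 0
            labels = est.labels_
            for cl in est.clusters_:
                for m in cl.members:
                    if not is_leading(pts[m, :2], cl, 1.5):
                        neigh = idx.neighbors(m)
                        assert (labels[neigh] == cl.id).all()


class TestEquivalenceAndEfficiency:
    def test_random_binary_images_match_dbscan(self, rng):
        for _ in range(20):
            pts = random_binary_points(rng, 25, 35)
            params = ClusterParams(eps=2.0, min_pts=4)
            labels, _, stats = fdbld_cluster(pts, params)
            assert same_partition(labels, brute_dbscan(pts, 2.0, 4))
            assert stats.fired <= len(pts)

    def test_solid_square_skips_queries(self):
        _, _, stats = fdbld_cluster(solid_square(20), ClusterParams(eps=1.5, min_pts=5))
        assert stats.skipped >= 1
        assert stats.fired < stats.total_points

    def test_monotone_growth_of_members(self):
        # member sets only grow: total members equals non-noise label count
        pts = solid_square(12)
        labels, clusters, _ = fdbld_cluster(pts, ClusterParams(eps=1.5, min_pts=5))
        assert sum(len(c.members) for c in clusters) == int((labels != NOISE).sum())
        # and every member is inside its cluster's boundary
        for c in clusters:
            for m in c.members:
                assert contains(c.gamma, pts[m, :2])

    def test_nd_noskip_identical_to_dbscan(self, rng):
        for _ in range(5):
            img = random_patchwork_image(rng, 24, 24)
            pts = image_points(img)
            params = ClusterParams(eps=0.06, min_pts=8, metric="nd", image_size=(24, 24))
            labels, _, _ = fdbld_cluster(pts, params, skip=False)
            assert np.array_equal(labels, dbscan(pts, params))

    def test_nd_skip_agreement_measured_on_flat_patches(self, rng):
        """On color-homogeneous clusters the conservative skip is exact."""
        disagreements = 0
        for _ in range(5):
            img = random_patchwork_image(rng, 24, 24)
            pts = image_points(img)
            params = ClusterParams(eps=0.06, min_pts=8, metric="nd", image_size=(24, 24))
            labels, _, _ = fdbld_cluster(pts, params, skip=True)
            ref = dbscan(pts, params)
            disagreements += int((labels != ref).sum())
        assert disagreements == 0
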