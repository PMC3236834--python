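import numpy as np
import pytest

from ndlesion.evalmetrics import count_pixels
from ndlesion.img_io import BinaryMask, RGBImage
from ndlesion.lesion import (
    LesionSegmenter,
    SelectionConfig,
    mask_to_contour,
    rasterize_contour,
    segment_lesion,
    select_lesion_clusters,
)


def mask_of(arr):
    return BinaryMask(np.asarray(arr, np.uint8))


class TestContourRoundTrip:
    def test_solid_square_single_polygon_edge_coords(self):
        m = np.zeros((6, 6), np.uint8)
        m[1:4, 1:4] = 1
        ps = mask_to_contour(mask_of(m))
        assert len(ps.polys) == 1
        assert set(ps.polys[0].exterior.coords[:-1]) == {(1, 1), (4, 1), (4, 4), (1, 4)}

    def test_two_disjoint_blobs_two_polygons(self):
        m = np.zeros((10, 10), np.uint8)
        m[1:3, 1:3] = 1
        m[6:9, 6:9] = 1
        assert len(mask_to_contour(mask_of(m)).polys) == 2

    def test_empty_mask_empty_set(self):
        ps = mask_to_contour(mask_of(np.zeros((4, 4))))
        assert ps.is_empty
        assert rasterize_contour(ps, (4, 4)).n_foreground == 0

    def test_round_trip_on_random_blobs(self, rng):
        from scipy.ndimage import binary_closing

        for _ in range(50):
            raw = rng.random((16, 16)) < 0.45
            m = binary_closing(raw).astype(np.uint8)
            mask = mask_of(m)
            back = rasterize_contour(mask_to_contour(mask), (16, 16))
            assert np.array_equal(back.data, mask.data)

    def test_round_trip_preserves_holes(self):
        m = np.ones((9, 9), np.uint8)
        m[3:6, 3:6] = 0  # donut
        mask = mask_of(m)
        back = rasterize_contour(mask_to_contour(mask), (9, 9))
        assert np.array_equal(back.data, mask.data)


class TestClusterSelection:
    def _img(self, gray_levels):
        arr = np.repeat(np.asarray(gray_levels, np.uint8)[..., None], 3, axis=-1)
        return RGBImage(arr)

    def test_dark_central_blob_beats_frame_spanning_background(self):
        grid = np.zeros((20, 20), np.int32)
        grid[:, :] = 1  # background cluster touches every border
        grid[8:13, 8:13] = 2  # central blob
        gray = np.full((20, 20), 200, np.uint8)
        gray[8:13, 8:13] = 60
        ids = select_lesion_clusters(grid, self._img(gray))
        assert ids == [2]

    def test_all_peripheral_empty_selection(self):
        grid = np.zeros((12, 12), np.int32)
        grid[0:12, 0:3] = 1  # flush with three borders
        ids = select_lesion_clusters(grid, self._img(np.full((12, 12), 100, np.uint8)))
        assert ids == []

    def test_min_area_filter(self):
        grid = np.zeros((30, 30), np.int32)
        grid[10, 10] = 1  # 1 px << 1% of 900
        grid[15:20, 15:20] = 2
        gray = np.full((30, 30), 200, np.uint8)
        gray[10, 10] = 5  # darkest but tiny
        gray[15:20, 15:20] = 80
        assert select_lesion_clusters(grid, self._img(gray)) == [2]

    def test_luminance_tie_broken_by_area(self):
        grid = np.zeros((30, 30), np.int32)
        grid[5:8, 5:8] = 1
        grid[15:21, 15:21] = 2  # same luminance, larger
        gray = np.full((30, 30), 220, np.uint8)
        gray[grid > 0] = 90
        assert select_lesion_clusters(grid, self._img(gray)) == [2]

    def test_pick_all_returns_every_survivor(self):
        grid = np.zeros((30, 30), np.int32)
        grid[4:10, 4:10] = 1
        grid[18:26, 18:26] = 2
        gray = np.full((30, 30), 200, np.uint8)
        gray[grid > 0] = 70
        ids = select_lesion_clusters(grid, self._img(gray), pick="all")
        assert ids == [1, 2]


class TestSegmentLesion:
    def test_nd_mode_recovers_clean_phantom(self, clean_phantom):
        img, truth = clean_phantom
        res = segment_lesion(img, mode="nd")
        assert res.status == "ok"
        c = count_pixels(res.mask, truth)
        # mask covers >= 95% of the true lesion
        assert c.tp / (c.tp + c.fn) >= 0.95

    def test_binary_mode_overlaps_phantom(self, clean_phantom):
        img, truth = clean_phantom
        res = segment_lesion(img, mode="binary")
        c = count_pixels(res.mask, truth)
        assert c.tp / (c.tp + c.fn) >= 0.95

    def test_noisy_phantom_nd_recovery(self, easy_phantom):
        img, truth = easy_phantom
        res = segment_lesion(img, mode="nd")
        c = count_pixels(res.mask, truth)
        assert c.tp / (c.tp + c.fn) >= 0.85

    def test_blank_image_empty_mask_with_warning(self):
        img = RGBImage(np.full((48, 48, 3), 180, np.uint8))
        with pytest.warns(UserWarning, match="no cluster"):
            res = segment_lesion(img, mode="nd", eps=0.02, min_pts=10)
        assert res.status == "empty"
        assert res.mask.n_foreground == 0

    def test_nd_mode_never_touches_intermeans(self, monkeypatch, clean_phantom):
        """Pre-processing independence: the ND pipeline must not read any
        threshold, so poisoning intermeans cannot affect it."""
        import ndlesion.lesion as lesion_mod

        def boom(*a, **k):
            raise AssertionError("intermeans used in ND mode")

        monkeypatch.setattr(lesion_mod.IntermeansThreshold, "fit", boom)
        img, _ = clean_phantom
        res = segment_lesion(img, mode="nd")
        assert res.status == "ok"
        with pytest.raises(AssertionError):
            segment_lesion(img, mode="binary")

    def test_threshold_override_used_in_binary_mode(self, clean_phantom):
        img, truth = clean_phantom
        res = segment_lesion(img, mode="binary", threshold=255.0)
        # everything foreground -> single frame-spanning cluster -> dropped
        assert res.params["threshold"] == 255.0

    def test_shrinking_eps_never_merges_nd_clusters(self, rng):
        """ε-neighborhood graphs are monotone in ε: clusters separate at a
        given ε stay separate (possibly fragmenting) at smaller ε."""
        from _oracles import image_points, random_patchwork_image

        from ndlesion.dbscan_ref import ClusterParams
        from ndlesion.fdbld import fdbld_cluster

        img = random_patchwork_image(rng, 24, 24)
        pts = image_points(img)
        big = fdbld_cluster(pts, ClusterParams(eps=0.08, min_pts=6, metric="nd", image_size=(24, 24)))[0]
        small = fdbld_cluster(pts, ClusterParams(eps=0.05, min_pts=6, metric="nd", image_size=(24, 24)))[0]
        for cid in np.unique(small):
            if cid <= 0:
                continue
            parents = big[small == cid]
            parents = parents[parents > 0]
            assert len(np.unique(parents)) <= 1


class TestEstimatorContract:
    def test_fitted_attributes_and_params(self, clean_phantom):
        img, _ = clean_phantom
        est = LesionSegmenter(mode="nd").fit(img)
        assert est.mask_.n_foreground > 0
        assert est.cluster_ids_
        assert est.result_.params["mode"] == "nd"
        p = est.get_params()
        assert p["mode"] == "nd" and "eps" in p

    def test_unknown_mode_raises(self, clean_phantom):
        with pytest.raises(ValueError, match="mode"):
            LesionSegmenter(mode="magic").fit(clean_phantom[0])
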