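"""End-to-end lesion border detection.

Two pipelines share the same clustering engine:

* ``nd`` mode (the headline method): cluster *all* pixels with the joint
  color+spatial normalized distance — no thresholding pre-processing —
  then pick the lesion cluster(s) among the non-peripheral candidates
  (lesions are dark, so the darkest surviving cluster wins);
* ``binary`` mode (the baseline): intermeans threshold → foreground
  pixels → spatial clustering → the union of surviving clusters.

The output is a binary lesion mask (the automatic border, AB) plus its
outline as pixel-edge polygons for comparison with manual borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union
from sklearn.base import BaseEstimator

from .dbscan_ref import NOISE
from .distances import NDWeights
from .fdbld import FDBLD, QueryStats
from .geometry import PolygonSet
from .img_io import BinaryMask, RGBImage, image_to_points, points_to_label_grid
from .preprocess import IntermeansThreshold, to_gray

#: Default clustering parameters per mode, tuned on synthetic phantoms
#: (see docs/methods.md); the paper-scale images would need their own ε.
ND_DEFAULTS = dict(eps=0.05, min_pts=70)
BINARY_DEFAULTS = dict(eps=1.5, min_pts=5)


@dataclass(frozen=True)
class SelectionConfig:
    """Rules deciding which clusters constitute the lesion."""

    min_area_frac: float = 0.01  # drop clusters below this image fraction
    border_touch_frac: float = 0.25  # drop clusters whose bbox hugs the frame
    top_k: int = 1  # darkest-k clusters kept in ND mode


@dataclass
class LesionResult:
    """Automatic border mask, its contour, and provenance of the run."""

    mask: BinaryMask
    contour: PolygonSet
    cluster_ids: list[int]
    params: dict
    status: str = "ok"  # "ok" | "empty"
    query_stats: QueryStats | None = None
    label_grid: np.ndarray | None = None


def _cluster_features(label_grid: np.ndarray, gray: np.ndarray):
    ids = np.unique(label_grid)
    ids = ids[ids > 0]
    feats = {}
    for cid in ids:
        sel = label_grid == cid
        ys, xs = np.nonzero(sel)
        feats[int(cid)] = dict(
            area=int(sel.sum()),
            bbox=(int(xs.min()), int(xs.max()), int(ys.min()), int(ys.max())),
            mean_lum=float(gray[sel].mean()),
        )
    return feats


def select_lesion_clusters(
    label_grid: np.ndarray,
    img: RGBImage,
    config: SelectionConfig | None = None,
    pick: str = "darkest",
) -> list[int]:
    """Choose lesion cluster ids from a labeled pixel grid.

    Filters: peripheral clusters (bounding box flush with the image frame
    over more than ``border_touch_frac`` of its perimeter — image-border
    regions are peripherals, not lesion) and clusters smaller than
    ``min_area_frac`` of the image are dropped. Among survivors,
    ``pick='darkest'`` returns the ``top_k`` lowest-mean-luminance
    clusters (ties broken by larger area), ``pick='all'`` returns all.
    """
    cfg = config or SelectionConfig()
    h, w = label_grid.shape
    gray = to_gray(img)
    feats = _cluster_features(label_grid, gray)
    survivors = []
    for cid, f in feats.items():
        x0, x1, y0, y1 = f["bbox"]
        bw, bh = x1 - x0 + 1, y1 - y0 + 1
        perimeter = 2 * (bw + bh)
        flush = 0
        if x0 == 0:
            flush += bh
        if x1 == w - 1:
            flush += bh
        if y0 == 0:
            flush += bw
        if y1 == h - 1:
            flush += bw
        if flush / perimeter > cfg.border_touch_frac:
            continue
        if f["area"] < cfg.min_area_frac * w * h:
            continue
        survivors.append(cid)
    if pick == "all":
        return sorted(survivors)
    survivors.sort(key=lambda c: (feats[c]["mean_lum"], -feats[c]["area"], c))
    return survivors[: cfg.top_k]


def mask_to_contour(mask: BinaryMask) -> PolygonSet:
    """Outline of the mask's foreground as pixel-edge polygons.

    Pixel (x, y) occupies the unit square [x, x+1]×[y, y+1]; the returned
    polygons (holes included, so ring-shaped regions round-trip exactly)
    satisfy rasterize(mask_to_contour(m)) == m.
    """
    ys, xs = np.nonzero(mask.data)
    if len(xs) == 0:
        return PolygonSet([])
    boxes = shapely.box(xs.astype(float), ys.astype(float), xs + 1.0, ys + 1.0)
    merged = unary_union(boxes.tolist()).simplify(0)  # drop collinear vertices
    parts = merged.geoms if merged.geom_type == "MultiPolygon" else [merged]
    return PolygonSet([Polygon(p) for p in parts])


def rasterize_contour(contour: PolygonSet, size: tuple[int, int]) -> BinaryMask:
    """Inverse of :func:`mask_to_contour`: pixel-center containment test."""
    w, h = size
    out = np.zeros((h, w), np.uint8)
    if contour.is_empty:
        return BinaryMask(out)
    ys, xs = np.mgrid[0:h, 0:w]
    cx, cy = xs + 0.5, ys + 0.5
    hit = np.zeros((h, w), bool)
    for poly in contour.polys:
        hit |= shapely.contains_xy(poly, cx, cy)
    return BinaryMask(hit.astype(np.uint8))


class LesionSegmenter(BaseEstimator):
    """Image → lesion mask estimator.

    Parameters
    ----------
    mode : 'nd' (color+spatial clustering of all pixels, no pre-processing)
        or 'binary' (intermeans threshold then spatial clustering).
    eps, min_pts : clustering parameters; per-mode defaults when None.
    weights : ND weight set (ND mode only).
    threshold : manual override of the intermeans threshold (binary mode).
    min_area_frac, border_touch_frac, top_k : cluster selection rules.
    skip : enable FDBLD query skipping.

    Attributes
    ----------
    mask_ : BinaryMask of the detected lesion (AB).
    contour_ : PolygonSet outline of the mask.
    cluster_ids_ : selected cluster ids.
    result_ : full :class:`LesionResult`.
    """

    def __init__(
        self,
        mode: str = "nd",
        eps: float | None = None,
        min_pts: int | None = None,
        weights: NDWeights | None = None,
        threshold: float | None = None,
        min_area_frac: float = 0.01,
        border_touch_frac: float = 0.25,
        top_k: int = 1,
        skip: bool = True,
    ):
        self.mode = mode
        self.eps = eps
        self.min_pts = min_pts
        self.weights = weights
        self.threshold = threshold
        self.min_area_frac = min_area_frac
        self.border_touch_frac = border_touch_frac
        self.top_k = top_k
        self.skip = skip

    # -- internals ---------------------------------------------------------

    def _resolved(self) -> dict:
        if self.mode not in ("nd", "binary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        defaults = ND_DEFAULTS if self.mode == "nd" else BINARY_DEFAULTS
        return dict(
            eps=self.eps if self.eps is not None else defaults["eps"],
            min_pts=self.min_pts if self.min_pts is not None else defaults["min_pts"],
        )

    def _empty_result(self, img: RGBImage, params: dict, stats=None) -> LesionResult:
        warnings.warn("no cluster qualified as lesion; returning empty mask")
        mask = BinaryMask(np.zeros((img.height, img.width), np.uint8))
        return LesionResult(
            mask=mask, contour=PolygonSet([]), cluster_ids=[], params=params,
            status="empty", query_stats=stats,
        )

    def fit(self, X: RGBImage, y=None):
        img = X if isinstance(X, RGBImage) else RGBImage(np.asarray(X))
        p = self._resolved()
        sel = SelectionConfig(
            min_area_frac=self.min_area_frac,
            border_touch_frac=self.border_touch_frac,
            top_k=self.top_k,
        )
        echo = dict(mode=self.mode, **p, skip=self.skip)

        if self.mode == "binary":
            gray = to_gray(img)
            if self.threshold is not None:
                t = float(self.threshold)
            else:
                t = IntermeansThreshold().fit(gray).threshold_
            echo["threshold"] = t
            fg = BinaryMask((gray <= t).astype(np.uint8), foreground_label="lesion")
            points = image_to_points(img, fg)
            metric = "euclidean"
            pick = "all"
        else:
            points = image_to_points(img)
            metric = "nd"
            pick = "darkest"

        if len(points) == 0:
            result = self._empty_result(img, echo)
        else:
            est = FDBLD(
                eps=p["eps"], min_pts=p["min_pts"], metric=metric,
                weights=self.weights, image_size=img.size, skip=self.skip,
            ).fit(points)
            grid = points_to_label_grid(points, est.labels_, img.size, fill=0)
            grid[grid == NOISE] = 0
            ids = select_lesion_clusters(grid, img, sel, pick=pick)
            if not ids:
                result = self._empty_result(img, echo, est.query_stats_)
                result.label_grid = grid
            else:
                mask = BinaryMask(np.isin(grid, ids).astype(np.uint8), "lesion")
                result = LesionResult(
                    mask=mask,
                    contour=mask_to_contour(mask),
                    cluster_ids=ids,
                    params=echo,
                    query_stats=est.query_stats_,
                    label_grid=grid,
                )

        self.mask_ = result.mask
        self.contour_ = result.contour
        self.cluster_ids_ = result.cluster_ids
        self.result_ = result
        return self


def segment_lesion(
    img: RGBImage, mode: str = "nd", **kwargs
) -> LesionResult:
    """Functional wrapper over :class:`LesionSegmenter`."""
    return LesionSegmenter(mode=mode, **kwargs).fit(img).result_
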