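"""Image and mask I/O plus the pixel-grid view consumed by the clustering.

Coordinate convention used throughout the package: the top-left pixel is
(0, 0), ``x`` indexes columns (rightward) and ``y`` indexes rows (downward),
both 0-based. Arrays are stored row-major, i.e. ``pixels[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image


class PixelPoint(NamedTuple):
    """One image pixel as a clustering datum: position plus color."""

    x: int
    y: int
    r: int = 0
    g: int = 0
    b: int = 0


@dataclass(frozen=True)
class RGBImage:
    """8-bit RGB raster; ``pixels`` has shape (height, width, 3), dtype uint8."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (h, w, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) — the (ω, h) pair used by the normalized distance."""
        return (self.width, self.height)


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel 0/1 grid; in memory 1 always marks the foreground.

    ``foreground_label`` records which semantic class the 1-pixels carry
    (e.g. "lesion" for the dark, below-threshold side of an intermeans
    split). On disk masks are written as 8-bit PNG with foreground = 255.
    """

    data: np.ndarray
    foreground_label: str = field(default="foreground", compare=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError(f"expected 2-D mask, got shape {d.shape}")
        d = d.astype(np.uint8, copy=False)
        if not np.isin(d, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "data", d)

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


def read_image(path: str | Path) -> RGBImage:
    """Read an 8-bit PNG or PPM image; grayscale is promoted to RGB.

    Raises OSError for unreadable files and ValueError for unsupported
    modes (palette images are expanded; >8-bit depths are rejected).
    """
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise ValueError(f"unsupported bit depth (mode {im.mode!r}); expected 8-bit")
        if im.mode == "P":
            im = im.convert("RGB")
        if im.mode == "L":
            im = im.convert("RGB")  # replicate gray into all three channels
        if im.mode == "RGBA":
            im = im.convert("RGB")
        if im.mode != "RGB":
            raise ValueError(f"unsupported image mode {im.mode!r}")
        return RGBImage(np.asarray(im, dtype=np.uint8))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as single-channel 8-bit PNG, foreground = 255."""
    Image.fromarray(mask.data * np.uint8(255), mode="L").save(path, format="PNG")


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask PNG written by :func:`write_mask` (values 0/255 or 0/1)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError(f"not a binary mask: pixel values {vals.tolist()}")
    return BinaryMask((arr > 0).astype(np.uint8))


def image_to_points(img: RGBImage, mask: BinaryMask | None = None) -> np.ndarray:
    """Flatten an image to an (n, 5) int array of (x, y, r, g, b) rows.

    Without a mask every pixel is emitted (the all-pixels view used by
    ND-mode clustering); with a mask only foreground pixels are kept
    (the binary-mode view). Order is deterministic row-major: y outer,
    x inner.
    """
    h, w = img.pixels.shape[:2]
    if mask is not None and (mask.height, mask.width) != (h, w):
        raise ValueError(
            f"mask dimensions {mask.width}x{mask.height} do not match "
            f"image {w}x{h}"
        )
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack(
        [xs.ravel(), ys.ravel(), img.pixels.reshape(-1, 3)]
    ).astype(np.int32)
    if mask is not None:
        pts = pts[mask.data.ravel().astype(bool)]
    return pts


def points_to_label_grid(
    points: np.ndarray, labels: np.ndarray, size: tuple[int, int], fill: int = 0
) -> np.ndarray:
    """Scatter per-point labels back onto the (h, w) pixel grid."""
    w, h = size
    grid = np.full((h, w), fill, dtype=np.int32)
    grid[points[:, 1], points[:, 0]] = labels
    return grid
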