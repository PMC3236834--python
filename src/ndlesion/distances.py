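"""Pixel distance functions.

Four metrics are provided: plain spatial Euclidean and Manhattan distances,
the normalized joint color+spatial distance (ND) that lets density-based
clustering run directly on color images, and its multispectral
generalization. The ND between pixels i and j of a ω×h image is

    d(i,j) = sqrt( (1/w1)·(w3·ΔR² + w4·ΔG² + w5·ΔB²) / (3·255²)
                 + (1/w2)·(Δx² + Δy²) / (ω² + h²) )

where w3, w4, w5 weight the R, G, B channels (default 1), and w1, w2 balance
the color block against the spatial block under the constraint
1/w1 + 1/w2 = 1 (default w1 = w2 = 2, an even split). 3·255² is the RGB
normalization constant; ω²+h² (the squared image diagonal) normalizes the
spatial part, so with default weights d < 1 for any pixel pair of the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: RGB channel normalization constant: three channels of range 255.
COLOR_NORM = 3 * 255**2

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class NDWeights:
    """Weights of the normalized distance.

    w1 scales the color block, w2 the spatial block (harmonic constraint
    1/w1 + 1/w2 = 1 keeps the metric normalized); w3, w4, w5 weight the
    individual R, G, B channels.
    """

    w1: float = 2.0
    w2: float = 2.0
    w3: float = 1.0
    w4: float = 1.0
    w5: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("w1 and w2 must be positive")
        if abs(1.0 / self.w1 + 1.0 / self.w2 - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"block weights must satisfy 1/w1 + 1/w2 = 1, got "
                f"1/{self.w1} + 1/{self.w2} = {1 / self.w1 + 1 / self.w2!r}"
            )
        if min(self.w3, self.w4, self.w5) < 0:
            raise ValueError("channel weights w3, w4, w5 must be non-negative")

    @property
    def channel(self) -> tuple[float, float, float]:
        return (self.w3, self.w4, self.w5)


def _xy(p: Sequence[float]) -> tuple[float, float]:
    return float(p[0]), float(p[1])


def euclidean(p: Sequence[float], q: Sequence[float]) -> float:
    """Spatial Euclidean distance between two pixels."""
    px, py = _xy(p)
    qx, qy = _xy(q)
    return math.hypot(px - qx, py - qy)


def manhattan(p: Sequence[float], q: Sequence[float]) -> float:
    """Spatial Manhattan (city-block) distance between two pixels."""
    px, py = _xy(p)
    qx, qy = _xy(q)
    return abs(px - qx) + abs(py - qy)


def normalized_distance(
    p: Sequence[float],
    q: Sequence[float],
    dims: tuple[int, int],
    weights: NDWeights | None = None,
) -> float:
    """Normalized color+spatial distance between two (x, y, r, g, b) pixels."""
    w = weights or NDWeights()
    omega, h = dims
    if omega <= 0 or h <= 0:
        raise ValueError("image dimensions must be positive")
    dr = float(p[2]) - float(q[2])
    dg = float(p[3]) - float(q[3])
    db = float(p[4]) - float(q[4])
    dx = float(p[0]) - float(q[0])
    dy = float(p[1]) - float(q[1])
    color = (w.w3 * dr * dr + w.w4 * dg * dg + w.w5 * db * db) / COLOR_NORM
    spatial = (dx * dx + dy * dy) / (omega * omega + h * h)
    return math.sqrt(color / w.w1 + spatial / w.w2)


def multispectral_distance(
    u: Sequence[float],
    v: Sequence[float],
    dims: tuple[int, int],
    channel_weights: Sequence[float] | None = None,
    channel_norm: float | Sequence[float] | None = None,
    w1: float = 2.0,
    w2: float = 2.0,
) -> float:
    """ND generalized to n spectral channels.

    ``u`` and ``v`` are (x, y, C_1, ..., C_n). ``channel_norm`` is either a
    single normalization constant for the summed weighted squared channel
    differences (the RGB case uses 3·255²) or one constant per channel, in
    which case each squared difference is normalized individually before
    summation. With n = 3 RGB channels, unit channel weights and norm
    3·255² this reduces exactly to :func:`normalized_distance`.
    """
    if len(u) != len(v):
        raise ValueError("spectral vectors must have the same channel count")
    n = len(u) - 2
    if n < 1:
        raise ValueError("need at least one spectral channel")
    if w1 <= 0 or w2 <= 0 or abs(1.0 / w1 + 1.0 / w2 - 1.0) > _WEIGHT_TOL:
        raise ValueError("block weights must satisfy 1/w1 + 1/w2 = 1")
    cw = np.ones(n) if channel_weights is None else np.asarray(channel_weights, float)
    if cw.shape != (n,):
        raise ValueError(f"expected {n} channel weights, got {cw.shape}")
    omega, h = dims
    dc = np.asarray(u[2:], float) - np.asarray(v[2:], float)
    if channel_norm is None:
        channel_norm = n * 255.0**2
    norm = np.asarray(channel_norm, float)
    if norm.ndim == 0:
        color = float(np.sum(cw * dc * dc)) / float(norm)
    else:
        if norm.shape != (n,):
            raise ValueError(f"expected {n} per-channel normalizers, got {norm.shape}")
        color = float(np.sum(cw * dc * dc / norm))
    dx = float(u[0]) - float(v[0])
    dy = float(u[1]) - float(v[1])
    spatial = (dx * dx + dy * dy) / (omega * omega + h * h)
    return math.sqrt(color / w1 + spatial / w2)


def spatial_reach(eps: float, dims: tuple[int, int], weights: NDWeights | None = None) -> float:
    """Largest pixel-space displacement compatible with an ND of ``eps``.

    Any pixel q with normalized_distance(p, q) <= eps satisfies
    sqrt(Δx²+Δy²) <= eps·sqrt(w2·(ω²+h²)): the color block is non-negative,
    so the spatial block alone bounds the displacement. Used to restrict
    ND region queries to a finite window.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    w = weights or NDWeights()
    omega, h = dims
    return eps * math.sqrt(w.w2 * (omega * omega + h * h))


# ---------------------------------------------------------------------------
# vectorized one-vs-many kernels used by the neighbor index


def nd_to_many(p: np.ndarray, Q: np.ndarray, dims: tuple[int, int], w: NDWeights) -> np.ndarray:
    """ND from one (x,y,r,g,b) row to each row of Q; vectorized."""
    omega, h = dims
    d = Q[:, :5].astype(np.float64) - np.asarray(p[:5], np.float64)
    cw = np.array(w.channel)
    color = (d[:, 2:5] ** 2 @ cw) / COLOR_NORM
    spatial = (d[:, 0] ** 2 + d[:, 1] ** 2) / (omega * omega + h * h)
    return np.sqrt(color / w.w1 + spatial / w.w2)


def euclidean_to_many(p: np.ndarray, Q: np.ndarray) -> np.ndarray:
    d = Q[:, :2].astype(np.float64) - np.asarray(p[:2], np.float64)
    return np.hypot(d[:, 0], d[:, 1])


def manhattan_to_many(p: np.ndarray, Q: np.ndarray) -> np.ndarray:
    d = Q[:, :2].astype(np.float64) - np.asarray(p[:2], np.float64)
    return np.abs(d[:, 0]) + np.abs(d[:, 1])
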