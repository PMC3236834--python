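"""Intermeans automatic thresholding (iterative two-means).

This is the pre-processing step of the binary pipeline: the RGB image is
reduced to luminance, a global threshold is found by iterating
T_{t+1} = (mean(gray <= T_t) + mean(gray > T_t)) / 2 from the global mean,
and pixels at or below the threshold (the dark side — lesions are dark)
become the foreground of a binary mask. The ND pipeline bypasses this
module entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .img_io import BinaryMask, RGBImage

#: ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of intermeans iteration."""

    threshold: float
    iterations: int
    converged: bool
    degenerate: bool = False  # constant image: one class empty at every T


def to_gray(img: RGBImage | np.ndarray) -> np.ndarray:
    """Per-pixel luminance 0.299R + 0.587G + 0.114B as float64."""
    px = img.pixels if isinstance(img, RGBImage) else np.asarray(img)
    return px.astype(np.float64) @ _LUMA


def intermeans_threshold(
    gray: np.ndarray, tol: float = 0.5, max_iter: int = 500
) -> ThresholdResult:
    """Iterative intermeans threshold of a grayscale grid.

    Starts at the global mean and sets the threshold halfway between the
    two class means until it moves by less than ``tol`` gray levels.
    A constant image is degenerate: the threshold is that constant.
    """
    g = np.asarray(gray, np.float64).ravel()
    if g.size == 0:
        raise ValueError("need at least one pixel")
    if g.min() == g.max():
        return ThresholdResult(float(g[0]), 1, True, degenerate=True)
    t = float(g.mean())
    for it in range(1, max_iter + 1):
        low = g[g <= t]
        high = g[g > t]
        if low.size == 0 or high.size == 0:
            # threshold drifted past the data; clamp to the occupied side
            return ThresholdResult(t, it, True, degenerate=True)
        t_new = (low.mean() + high.mean()) / 2.0
        if abs(t_new - t) < tol:
            return ThresholdResult(float(t_new), it, True)
        t = float(t_new)
    return ThresholdResult(t, max_iter, False)


def binarize(gray: np.ndarray, threshold: float) -> BinaryMask:
    """Mask whose foreground is the dark side: pixels with gray <= T.

    Ties at exactly T go to the foreground so the lesion never loses
    boundary pixels.
    """
    g = np.asarray(gray, np.float64)
    return BinaryMask((g <= threshold).astype(np.uint8), foreground_label="lesion")


class IntermeansThreshold(BaseEstimator, TransformerMixin):
    """Estimator wrapper: fit finds the threshold, transform binarizes.

    Parameters
    ----------
    tol : convergence tolerance in gray levels.

    Attributes
    ----------
    threshold_ : the converged threshold.
    n_iter_ : iterations used.
    converged_, degenerate_ : convergence flags.
    """

    def __init__(self, tol: float = 0.5):
        self.tol = tol

    def _as_gray(self, X) -> np.ndarray:
        if isinstance(X, RGBImage):
            return to_gray(X)
        X = np.asarray(X)
        if X.ndim == 3:
            return to_gray(RGBImage(X))
        return X.astype(np.float64)

    def fit(self, X, y=None):
        res = intermeans_threshold(self._as_gray(X), tol=self.tol)
        self.threshold_ = res.threshold
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.degenerate_ = res.degenerate
        return self

    def transform(self, X) -> BinaryMask:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("call fit before transform")
        return binarize(self._as_gray(X), self.threshold_)
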