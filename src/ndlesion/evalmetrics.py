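"""Segmentation evaluation: precision, recall, XOR border error.

The automatic border mask (AB) is compared pixel-wise against a manual
ground-truth mask (MB). Border error is the XOR measure customary in
lesion-border work:

    BE = 100 · |AB ⊕ MB| / |MB| = 100 · (fp + fn) / (tp + fn)

reported on the 0–100 percent scale (it can exceed 100 when the automatic
mask grossly over-segments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .img_io import BinaryMask

#: Sentinel for ratios with an empty denominator (e.g. precision of an
#: empty prediction). NaN rather than 0 so empty masks are never rewarded.
UNDEFINED = math.nan


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    border_error: float  # percent


def _pair(ab: BinaryMask, mb: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    a, m = ab.data.astype(bool), mb.data.astype(bool)
    if a.shape != m.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {m.shape}")
    return a, m


def count_pixels(ab: BinaryMask, mb: BinaryMask) -> EvalCounts:
    """Confusion counts of predicted (AB) vs manual (MB) foreground."""
    a, m = _pair(ab, mb)
    tp = int(np.sum(a & m))
    fp = int(np.sum(a & ~m))
    fn = int(np.sum(~a & m))
    tn = a.size - tp - fp - fn
    return EvalCounts(tp, fp, fn, tn)


def precision_recall(c: EvalCounts) -> tuple[float, float]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn); NaN when undefined."""
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else UNDEFINED
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else UNDEFINED
    return precision, recall


def border_error(ab: BinaryMask, mb: BinaryMask) -> float:
    """XOR border error in percent: 100·(fp+fn)/|MB|. Requires |MB| > 0."""
    c = count_pixels(ab, mb)
    denom = c.tp + c.fn
    if denom == 0:
        raise ValueError("border error undefined for an empty manual mask")
    return 100.0 * (c.fp + c.fn) / denom


def evaluate(ab: BinaryMask, mb: BinaryMask) -> EvalReport:
    """Full report for one mask pair."""
    c = count_pixels(ab, mb)
    p, r = precision_recall(c)
    return EvalReport(precision=p, recall=r, border_error=border_error(ab, mb))
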