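"""Contour-agreement metrics (MAD, DSC) and classification rates.

MAD is the symmetric mean of directed nearest-point distances between two
contours, evaluated on dense (1-px arc step) resamplings of both; DSC is the
Dice overlap of the rasterized interiors on the native pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask

from .contour import Contour, densify


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_dense(contour, closed: bool = True) -> np.ndarray:
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    if len(pts) == 0:
        raise ValueError("empty contour")
    if len(pts) == 1:
        return pts
    return densify(pts, step=1.0, closed=closed)


def mad(contour_a, contour_b, closed: bool = True) -> float:
    """Symmetric mean absolute contour distance in pixels.

    Both inputs are densely resampled at 1-px arc steps before the directed
    mean nearest-point distances are averaged.
    """
    a = _as_dense(contour_a, closed)
    b = _as_dense(contour_b, closed)
    d_ab = cKDTree(b).query(a)[0].mean()
    d_ba = cKDTree(a).query(b)[0].mean()
    return 0.5 * float(d_ab + d_ba)


def dsc(contour_a, contour_b, shape=None) -> float:
    """Dice similarity coefficient of the rasterized polygon interiors."""
    a = contour_a.points if isinstance(contour_a, Contour) else np.asarray(contour_a, float)
    b = contour_b.points if isinstance(contour_b, Contour) else np.asarray(contour_b, float)
    if abs(Contour(a).signed_area()) + abs(Contour(b).signed_area()) == 0:
        raise ValueError("both polygons rasterize to zero area")
    if shape is None:
        hi = np.ceil(np.vstack([a, b]).max(axis=0)).astype(int) + 2
        shape = (int(hi[1]), int(hi[0]))
    # polygon2mask expects (row, col) vertex order
    mask_a = polygon2mask(shape, a[:, ::-1])
    mask_b = polygon2mask(shape, b[:, ::-1])
    denom = mask_a.sum() + mask_b.sum()
    if denom == 0:
        raise ValueError("both polygons rasterize to zero area")
    return float(2.0 * np.logical_and(mask_a, mask_b).sum() / denom)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total, as a percentage."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP), as a percentage."""
    if cm.tp + cm.fp == 0:
        raise ValueError("precision undefined: no positive predictions")
    return 100.0 * cm.tp / (cm.tp + cm.fp)
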