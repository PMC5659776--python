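"""Intensity-template training and coarse-to-fine tendon localization.

A mean intensity template of the tendon region is built from training images
aligned (similarity transform) onto a reference tendon contour.  At test
time the template is matched coarse-to-fine: block search by mean absolute
difference (SAD) at half resolution, then Powell refinement of a similarity
transform at full resolution.  The reference contour mapped through the
refined transform initializes the active shape model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import transform as sk_transform

from .contour import Contour, ContourError
from .optimize import powell_minimize
from .shape_model import apply_pose, pose_from_alignment
from .texture import bilinear_sample

log = logging.getLogger(__name__)

#: template crop margin as a fraction of the tendon bounding box, per side
TEMPLATE_MARGIN_FRAC = 0.4
#: sliding-block stride as a fraction of the block size.  1/8 keeps the
#: worst-case block misalignment small enough that the true block always
#: beats unstructured background in SAD (a 1/4 stride provably does not)
BLOCK_STRIDE_FRAC = 0.125


@dataclass
class IntensityTemplate:
    """Mean aligned tendon-region image plus its reference contour."""

    pixels: np.ndarray
    reference_contour: Contour
    n_training: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        pts = self.reference_contour.points
        h, w = self.pixels.shape
        if (pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5
                or pts[:, 0].max() > w - 0.5 or pts[:, 1].max() > h - 0.5):
            raise ContourError("reference contour must lie inside the template crop")


def sad(block_a: np.ndarray, template_b: np.ndarray) -> float:
    """Mean absolute intensity difference between two equal-size blocks."""
    a = np.asarray(block_a, dtype=float)
    b = np.asarray(template_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def _crop_box(contour: Contour, shape, margin_frac: float):
    pts = contour.points
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    mx = margin_frac * (x1 - x0)
    my = margin_frac * (y1 - y0)
    c0 = max(0, int(np.floor(x0 - mx)))
    r0 = max(0, int(np.floor(y0 - my)))
    c1 = min(shape[1], int(np.ceil(x1 + mx)) + 1)
    r1 = min(shape[0], int(np.ceil(y1 + my)) + 1)
    return r0, r1, c0, c1


def train_template(images, contours, reference_index: int = 0,
                   margin_frac: float = TEMPLATE_MARGIN_FRAC) -> IntensityTemplate:
    """Average training images aligned onto the reference tendon contour.

    Every other training image is warped by the similarity transform mapping
    its contour onto the reference contour, and the per-pixel mean over all
    aligned images is cropped around the reference tendon (bounding box plus
    a 40% margin per side).  Pixels not covered by every warp are averaged
    over the images that do cover them.
    """
    if len(images) != len(contours) or len(images) < 1:
        raise ValueError("need equal, nonzero numbers of training images and contours")
    ref_img = np.asarray(images[reference_index], dtype=float)
    ref_contour = contours[reference_index]
    acc = np.zeros_like(ref_img)
    cover = np.zeros_like(ref_img)
    for idx, (img, con) in enumerate(zip(images, contours)):
        img = np.asarray(img, dtype=float)
        if idx == reference_index:
            warped = img
            mask = np.ones_like(img)
        else:
            tf = sk_transform.estimate_transform("similarity",
                                                 src=con.points, dst=ref_contour.points)
            warped = sk_transform.warp(img, tf.inverse, output_shape=ref_img.shape,
                                       order=1, mode="constant", cval=np.nan,
                                       preserve_range=True)
            mask = (~np.isnan(warped)).astype(float)
            if mask.min() == 0:
                log.info("training image %d does not cover the full reference crop", idx)
            warped = np.nan_to_num(warped)
        acc += warped * mask
        cover += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cover > 0, acc / np.maximum(cover, 1e-12), 0.0)
    r0, r1, c0, c1 = _crop_box(ref_contour, ref_img.shape, margin_frac)
    crop = mean[r0:r1, c0:c1]
    ref_in_crop = Contour(ref_contour.points - np.array([c0, r0]),
                          pixel_spacing_mm=ref_contour.pixel_spacing_mm)
    return IntensityTemplate(pixels=crop, reference_contour=ref_in_crop,
                             n_training=len(images))


def _downsample2(image: np.ndarray) -> np.ndarray:
    """2x2-mean downsampling (odd trailing row/column dropped)."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2])


def coarse_locate(image: np.ndarray, template: IntensityTemplate):
    """Half-resolution sliding-block SAD search for the template.

    Both the image and the template are downsampled by 2x2 averaging; blocks
    of template size are scanned with stride 1/4 of the block size, and the
    minimum-SAD block wins (ties broken toward the smallest (row, col)).

    Returns the full-resolution (x, y) origin of the winning block.
    """
    small_img = _downsample2(image)
    small_tpl = _downsample2(template.pixels)
    th, tw = small_tpl.shape
    ih, iw = small_img.shape
    if th > ih or tw > iw:
        raise ValueError("template does not fit in the image at half resolution")
    stride_r = max(1, int(round(th * BLOCK_STRIDE_FRAC)))
    stride_c = max(1, int(round(tw * BLOCK_STRIDE_FRAC)))
    # edge-flush positions are appended so the blocks tile the whole image
    rows = sorted(set(range(0, ih - th + 1, stride_r)) | {ih - th})
    cols = sorted(set(range(0, iw - tw + 1, stride_c)) | {iw - tw})
    best = (np.inf, 0, 0)
    for r in rows:
        for c in cols:
            v = sad(small_img[r:r + th, c:c + tw], small_tpl)
            if v < best[0] - 1e-12:
                best = (v, r, c)
    _, r, c = best
    return (2 * c, 2 * r)


def _warped_template_sad(image: np.ndarray, template: IntensityTemplate,
                         origin_xy, pose_vec) -> float:
    """SAD between the similarity-warped template and the image."""
    tx, ty, s, theta = pose_vec
    th, tw = template.pixels.shape
    yy, xx = np.mgrid[0:th, 0:tw].astype(float)
    grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
    center = np.array([(tw - 1) / 2.0, (th - 1) / 2.0])
    # rotate/scale about the template centre, then translate to the origin
    rel = grid - center
    c, si = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -si], [si, c]])
    mapped = s * rel @ rot.T + center + np.array([origin_xy[0] + tx, origin_xy[1] + ty])
    vals = bilinear_sample(np.asarray(image, float), mapped)
    return float(np.mean(np.abs(vals - template.pixels.ravel())))


def fine_locate(image: np.ndarray, template: IntensityTemplate, coarse_origin_xy):
    """Powell refinement of a similarity transform at full resolution.

    Minimizes SAD between the warped template and the image over
    (tx, ty, scale, rotation), starting at the coarse origin with identity
    scale and rotation.

    Returns
    -------
    transform : (tx, ty, scale, rotation)
        Offsets are relative to the coarse origin.
    initial_contour : Contour
        The template's reference contour mapped through the transform.
    final_sad : float
    """
    def objective(v):
        return _warped_template_sad(image, template, coarse_origin_xy, v)

    x = powell_minimize(objective, np.array([0.0, 0.0, 1.0, 0.0]))
    tx, ty, s, theta = (float(x[0]), float(x[1]), float(x[2]), float(x[3]))
    th, tw = template.pixels.shape
    center = np.array([(tw - 1) / 2.0, (th - 1) / 2.0])
    rel = template.reference_contour.points - center
    pts = apply_pose(rel, (0.0, 0.0, s, theta)) + center \
        + np.array([coarse_origin_xy[0] + tx, coarse_origin_xy[1] + ty])
    contour = Contour(pts, pixel_spacing_mm=template.reference_contour.pixel_spacing_mm)
    return (tx, ty, s, theta), contour, objective(x)


def manual_roi_override(image: np.ndarray, box, template: IntensityTemplate) -> Contour:
    """Map the reference contour into a user-supplied (x, y, w, h) box.

    Bypasses coarse/fine matching for images where automatic template
    matching fails (for example multi-tendon scans).
    """
    x, y, w, h = box
    if w <= 0 or h <= 0:
        raise ValueError(f"degenerate ROI box {box}")
    ih, iw = np.asarray(image).shape
    if x < 0 or y < 0 or x + w > iw or y + h > ih:
        raise ValueError(f"ROI box {box} outside image {iw}x{ih}")
    th, tw = template.pixels.shape
    sx = w / tw
    sy = h / th
    pts = template.reference_contour.points * np.array([sx, sy]) + np.array([x, y])
    return Contour(pts, pixel_spacing_mm=template.reference_contour.pixel_spacing_mm)


def localization_pose(template: IntensityTemplate, initial_contour: Contour):
    """Similarity pose mapping the reference contour onto an initial contour."""
    return pose_from_alignment(template.reference_contour.points, initial_contour.points)
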