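"""The ATASM objective: five energy terms, adaptive weights, total energy.

Each of the 20 control points contributes five terms:

* ``curvature`` — interior angle at the point (radians; straighter is larger,
  hence preferred under maximization),
* ``area_grad`` — mean of an inner 3x3 window minus an outer 3x3 window on
  the normal (bright-inside/dark-outside for the tendon; sign flipped for the
  sheath, which is dark inside),
* ``line_grad`` — same contrast with 5x1 line masks along the normal,
* ``gabor`` / ``laws`` — negative squared difference between the trained
  texture profile and the profile sampled on the current contour (a global
  sum split into per-point partial sums so it can be weighted per point; with
  all weights 1 the weighted total reduces to the plain global sum).

The weight of term ``k`` at point ``i`` is learned from training images: the
term is evaluated at 21 positions on the search line through the true
boundary point (+-10 px along the normal, step 1); writing ``F`` for the
value at the true boundary, ``F~`` for the line maximum and ``sigma`` for the
line standard deviation, the weight is the training-set mean of
``sigma * F / F~`` — large when the term peaks at the true boundary and
varies strongly along the line, i.e. when it is informative there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contour import Contour, outward_normals
from .texture import (
    ENERGY_FEATURES,
    FEATURE_GABOR,
    FEATURE_LAWS,
    PROFILE_OFFSETS,
    TextureProfileModel,
    bilinear_sample,
    energy_texture_images,
)

log = logging.getLogger(__name__)

TERM_NAMES = ("curvature", "area_grad", "line_grad", "gabor", "laws")
N_TERMS = 5

#: gradient window centres sit +-2 px along the normal
GRAD_OFFSET = 2.0
#: line-gradient mask: 5 samples at 1..5 px along the normal, each side
LINE_OFFSETS = np.arange(1.0, 6.0)
#: weight-training search line: +-10 px, step 1 (21 samples)
SEARCH_LINE = np.arange(-10.0, 11.0)

_WINDOW_3X3 = np.stack(np.meshgrid(np.arange(-1.0, 2.0), np.arange(-1.0, 2.0)),
                       axis=-1).reshape(-1, 2)


@dataclass
class EnergyVector:
    """5x20 matrix of per-term, per-point energy values."""

    values: np.ndarray
    contour: Contour

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_TERMS, self.contour.n_points):
            raise ValueError(f"energy matrix must be (5, n_points); got {self.values.shape}")


@dataclass
class EnergyWeights:
    """5x20 nonnegative adaptive weights, one per term per control point."""

    weights: np.ndarray
    target: str = "tendon"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("energy weights must be finite and nonnegative")

    @classmethod
    def uniform(cls, n_points: int = 20, target: str = "tendon") -> "EnergyWeights":
        return cls(np.ones((N_TERMS, n_points)), target=target)


# ---------------------------------------------------------------------------
# scalar term implementations (reference forms used by tests and training)
# ---------------------------------------------------------------------------

def curvature_term(contour: Contour, i: int) -> float:
    """Interior angle at control point ``i`` in [0, pi]."""
    pts = contour.points
    n = len(pts)
    v1 = pts[(i + 1) % n] - pts[i]
    v2 = pts[(i - 1) % n] - pts[i]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        log.warning("coincident neighbour points at control point %d; angle set to pi", i)
        return float(np.pi)
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(c))


def _grad_sign(target: str) -> float:
    if target == "tendon":
        return 1.0
    if target == "sheath":
        return -1.0
    raise ValueError(f"unknown target '{target}'")


def area_gradient_term(image: np.ndarray, contour: Contour, i: int,
                       target: str = "tendon") -> float:
    """Inner minus outer 3x3-window mean at +-2 px on the normal (sign per target)."""
    normal = outward_normals(contour)[i]
    p = contour.points[i]
    inner = bilinear_sample(image, p - GRAD_OFFSET * normal + _WINDOW_3X3).mean()
    outer = bilinear_sample(image, p + GRAD_OFFSET * normal + _WINDOW_3X3).mean()
    return _grad_sign(target) * float(inner - outer)


def line_gradient_term(image: np.ndarray, contour: Contour, i: int,
                       target: str = "tendon") -> float:
    """Inner minus outer 5x1-line mean along the normal (sign per target)."""
    normal = outward_normals(contour)[i]
    p = contour.points[i]
    inner = bilinear_sample(image, p - LINE_OFFSETS[:, None] * normal).mean()
    outer = bilinear_sample(image, p + LINE_OFFSETS[:, None] * normal).mean()
    return _grad_sign(target) * float(inner - outer)


def _texture_partials(tex_values: np.ndarray, model_profile: np.ndarray,
                      sample_xy: np.ndarray) -> np.ndarray:
    """Per-point partial sums of the negative squared profile difference."""
    test = bilinear_sample(tex_values, sample_xy)          # (..., n_pts, 5)
    model = model_profile.reshape(-1, len(PROFILE_OFFSETS))
    return -np.sum((model - test) ** 2, axis=-1)


def gabor_energy(profile_model: TextureProfileModel, contour: Contour,
                 image: np.ndarray) -> float:
    """Negative SSD between the trained and current Gabor 0-deg profiles."""
    ev = EnergyEvaluator(image, profile_model, target="tendon")
    return float(ev.terms(contour).values[TERM_NAMES.index("gabor")].sum())


def laws_energy(profile_model: TextureProfileModel, contour: Contour,
                image: np.ndarray) -> float:
    """Negative SSD between the trained and current Laws E5L5 profiles."""
    ev = EnergyEvaluator(image, profile_model, target="tendon")
    return float(ev.terms(contour).values[TERM_NAMES.index("laws")].sum())


def total_energy(energy: EnergyVector, weights: EnergyWeights) -> float:
    """Weighted double sum ``sum_k sum_i w_ik F_ik``."""
    if energy.values.shape != weights.weights.shape:
        raise ValueError(
            f"shape mismatch: energy {energy.values.shape} vs weights {weights.weights.shape}"
        )
    return float(np.sum(energy.values * weights.weights))


# ---------------------------------------------------------------------------
# vectorized evaluator
# ---------------------------------------------------------------------------

def _batch_normals(pts: np.ndarray) -> np.ndarray:
    """Outward unit normals for a batch of closed contours (n, k, 2)."""
    tan = np.roll(pts, -1, axis=1) - np.roll(pts, 1, axis=1)
    nrm = np.stack([tan[..., 1], -tan[..., 0]], axis=-1)
    lengths = np.linalg.norm(nrm, axis=-1, keepdims=True)
    lengths[lengths == 0] = 1.0
    nrm = nrm / lengths
    away = pts - pts.mean(axis=1, keepdims=True)
    flip = np.sum(nrm * away, axis=-1, keepdims=True) < 0
    return np.where(flip, -nrm, nrm)


def _batch_curvature(pts: np.ndarray) -> np.ndarray:
    v1 = np.roll(pts, -1, axis=1) - pts
    v2 = np.roll(pts, 1, axis=1) - pts
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    denom = n1 * n2
    dot = np.sum(v1 * v2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.clip(dot / denom, -1.0, 1.0)
    ang = np.arccos(c)
    return np.where(denom == 0, np.pi, ang)


class EnergyEvaluator:
    """Evaluates the 5x20 energy matrix on one image, batched over contours.

    Texture images are computed once per source image; all contour-dependent
    sampling is vectorized so whole GA populations can be scored at once.
    """

    def __init__(self, image: np.ndarray, profile_model: TextureProfileModel | None,
                 target: str = "tendon"):
        self.image = np.asarray(image, dtype=float)
        self.target = target
        self.sign = _grad_sign(target)
        self.profile_model = profile_model
        tex = energy_texture_images(self.image)
        self.tex_gabor = tex[FEATURE_GABOR].values
        self.tex_laws = tex[FEATURE_LAWS].values

    def batch_terms(self, pts: np.ndarray) -> np.ndarray:
        """(n, 5, n_points) energy matrices for contour batches (n, n_points, 2)."""
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 2
        if single:
            pts = pts[None]
        n, k, _ = pts.shape
        normals = _batch_normals(pts)

        curv = _batch_curvature(pts)

        inner_ctr = pts - GRAD_OFFSET * normals
        outer_ctr = pts + GRAD_OFFSET * normals
        win = _WINDOW_3X3[None, None, :, :]
        area = (bilinear_sample(self.image, inner_ctr[:, :, None, :] + win).mean(axis=-1)
                - bilinear_sample(self.image, outer_ctr[:, :, None, :] + win).mean(axis=-1))

        line_off = LINE_OFFSETS[None, None, :, None]
        line = (bilinear_sample(self.image,
                                pts[:, :, None, :] - line_off * normals[:, :, None, :]).mean(axis=-1)
                - bilinear_sample(self.image,
                                  pts[:, :, None, :] + line_off * normals[:, :, None, :]).mean(axis=-1))

        prof_xy = (pts[:, :, None, :]
                   + PROFILE_OFFSETS[None, None, :, None] * normals[:, :, None, :])
        if self.profile_model is not None:
            gab = _texture_partials(self.tex_gabor,
                                    self.profile_model.mean_profiles[FEATURE_GABOR], prof_xy)
            law = _texture_partials(self.tex_laws,
                                    self.profile_model.mean_profiles[FEATURE_LAWS], prof_xy)
        else:
            gab = np.zeros((n, k))
            law = np.zeros((n, k))

        out = np.stack([curv, self.sign * area, self.sign * line, gab, law], axis=1)
        return out[0] if single else out

    def terms(self, contour: Contour) -> EnergyVector:
        return EnergyVector(self.batch_terms(contour.points), contour)

    def total(self, contour: Contour, weights: EnergyWeights) -> float:
        return total_energy(self.terms(contour), weights)

    def batch_total(self, pts: np.ndarray, weights: EnergyWeights) -> np.ndarray:
        vals = self.batch_terms(pts)
        return np.einsum("nkp,kp->n", vals, weights.weights)


# ---------------------------------------------------------------------------
# adaptive weight training
# ---------------------------------------------------------------------------

def weights_from_line_table(line_vals: np.ndarray, true_index: int) -> np.ndarray:
    """Weight contribution of one image from its search-line value table.

    ``line_vals`` has shape ``(..., n_line)``; for every leading cell the
    contribution is ``sigma * F / F~`` with ``F`` the value at
    ``true_index``, ``F~`` the line maximum and ``sigma`` the line standard
    deviation.  Cells with a zero maximum or a negative/undefined ratio
    contribute 0.
    """
    line_vals = np.asarray(line_vals, dtype=float)
    f_true = line_vals[..., true_index]
    f_max = line_vals.max(axis=-1)
    sigma = line_vals.std(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = sigma * f_true / f_max
    contrib = np.where(f_max == 0, 0.0, contrib)
    contrib = np.where(np.isfinite(contrib), contrib, 0.0)
    return np.maximum(contrib, 0.0)


def train_weights(images, contours, profile_model: TextureProfileModel,
                  target: str = "tendon",
                  search_line: np.ndarray = SEARCH_LINE) -> EnergyWeights:
    """Learn the 5x20 adaptive weights from training image/contour pairs.

    For every term and control point, the term is evaluated at each of the 21
    search-line positions obtained by sliding that point along its outward
    normal while the rest of the contour stays at the ground truth.  The
    weight is the training-set mean of ``sigma * F / F~`` (floored at 0;
    images with a zero line maximum contribute 0).
    """
    if len(images) != len(contours) or len(images) < 1:
        raise ValueError("need equal, nonzero numbers of training images and contours")
    d0 = int(np.flatnonzero(search_line == 0.0)[0])
    per_image = []
    for image, contour in zip(images, contours):
        ev = EnergyEvaluator(image, profile_model, target=target)
        pts = contour.points
        k = len(pts)
        normals = outward_normals(contour)
        # one displaced contour per (point, line position)
        batch = np.broadcast_to(pts, (k, len(search_line), k, 2)).copy()
        idx = np.arange(k)
        batch[idx, :, idx, :] = (pts[:, None, :]
                                 + search_line[None, :, None] * normals[:, None, :])
        vals = ev.batch_terms(batch.reshape(-1, k, 2)).reshape(k, len(search_line), N_TERMS, k)
        # term value at the displaced point itself
        line_vals = vals[idx, :, :, idx]            # (k, n_line, 5)
        line_vals = np.moveaxis(line_vals, -1, 0)   # (5, k, n_line)
        n_zero = int(np.sum(line_vals.max(axis=-1) == 0))
        if n_zero:
            log.info("%d term/point cells had zero line maximum; contribution set to 0", n_zero)
        per_image.append(weights_from_line_table(line_vals, d0))
    weights = np.mean(per_image, axis=0)
    return EnergyWeights(weights, target=target)
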