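"""End-to-end tendon and synovial-sheath segmentation.

:class:`AtasmSegmenter` is the trainable front end: ``fit`` learns the shape
model, texture profile model, adaptive energy weights and (for the tendon)
the intensity template from training image/contour pairs; ``predict``
segments new images by template localization followed by alternating Powell
pose refinement and GA shape search of the weighted energy.

Sheath post-processing replaces the invisible lower sheath boundary by the
lower tendon arc (within 30 degrees of the downward vertical, measured from
the tendon centroid) and bridges the gaps to the fitted upper boundary with
one parabola per side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .contour import Contour, ContourError, densify, polygon_is_simple
from .energy import EnergyEvaluator, EnergyWeights, train_weights
from .localization import (
    IntensityTemplate,
    coarse_locate,
    fine_locate,
    manual_roi_override,
    train_template,
)
from .optimize import GAConfig, alternate_optimize
from .shape_model import PointDistributionModel, ShapeParams, pose_from_alignment
from .texture import TextureProfileModel, build_texture_model

log = logging.getLogger(__name__)

#: half-angle (degrees) of the lower-tendon arc adopted as lower sheath boundary
LOWER_ARC_DEG = 30.0
#: half-angle (degrees) of the wedge removed from the fitted sheath contour
UPPER_CUT_DEG = 60.0
#: clear/fuzzy decision: 15x15 windows centred +-8 px from the bottom point
GROUP_WINDOW = 15
GROUP_OFFSET = 8
GROUP_THRESHOLD = 30.0


@dataclass
class BoundaryGroup:
    """Clear/fuzzy bottom-boundary label with the measured window contrast."""

    label: str
    window_contrast: float


@dataclass
class SegmentationResult:
    tendon: Contour | None
    sheath: Contour | None = None            # raw fitted sheath contour
    sheath_upper: np.ndarray | None = None   # open polyline
    sheath_lower: np.ndarray | None = None   # open polyline on the tendon boundary
    sheath_closed: np.ndarray | None = None  # closed polyline after interpolation
    group: BoundaryGroup | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sheath post-processing
# ---------------------------------------------------------------------------

def _down_angles(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Angle of each point's direction from ``center``, measured from +y (down)."""
    d = points - center
    return np.arctan2(d[:, 0], d[:, 1])


def lower_sheath_from_tendon(tendon: Contour) -> np.ndarray:
    """Lower tendon arc strictly within 30 degrees of the downward vertical.

    Returned as an open polyline ordered left to right.
    """
    dense = densify(tendon.points, step=0.5, closed=True)
    ang = _down_angles(dense, tendon.centroid())
    keep = np.abs(ang) < np.deg2rad(LOWER_ARC_DEG)
    if not keep.any():
        raise ContourError("degenerate tendon shape: empty lower arc")
    pts = dense[keep]
    return pts[np.argsort(ang[keep])]


def _upper_sheath_arc(sheath: Contour, center: np.ndarray) -> np.ndarray:
    """Fitted sheath contour with a +-60-degree bottom wedge removed.

    Ordered right endpoint -> top -> left endpoint.
    """
    dense = densify(sheath.points, step=0.5, closed=True)
    ang = _down_angles(dense, center)
    keep = np.abs(ang) >= np.deg2rad(UPPER_CUT_DEG)
    if not keep.any():
        raise ContourError("degenerate sheath shape: empty upper arc")
    # rotate so the kept arc is contiguous
    gap = np.flatnonzero(~keep)
    if len(gap):
        start = (gap[-1] + 1) % len(dense)
        order = (np.arange(len(dense)) + start) % len(dense)
        dense, keep = dense[order], keep[order]
        arc = dense[: int(np.argmin(keep))] if not keep.all() else dense
    else:
        arc = dense
    # orient right -> left (descending angle from +y on the right side)
    if _down_angles(arc[:1], center)[0] < _down_angles(arc[-1:], center)[0]:
        arc = arc[::-1]
    return arc


def _side_parabola(upper_pt, upper_tangent, lower_pt):
    """Parabola x = a y^2 + b y + c through both endpoints, tangent-matched.

    ``upper_tangent`` is dx/dy at the upper endpoint.  Sampled at 1-px y
    steps from the upper to the lower endpoint.
    """
    xu, yu = upper_pt
    xl, yl = lower_pt
    if abs(yl - yu) < 1e-9:
        return np.array([upper_pt, lower_pt])
    m = np.array([[yu**2, yu, 1.0], [yl**2, yl, 1.0], [2 * yu, 1.0, 0.0]])
    rhs = np.array([xu, xl, upper_tangent])
    a, b, c = np.linalg.solve(m, rhs)
    n = max(2, int(np.ceil(abs(yl - yu))) + 1)
    ys = np.linspace(yu, yl, n)
    xs = a * ys**2 + b * ys + c
    return np.stack([xs, ys], axis=1)


def _endpoint_tangent(arc: np.ndarray, at_start: bool) -> float:
    """dx/dy near one end of a polyline (averaged over a few points)."""
    k = min(6, len(arc) - 1)
    seg = arc[:k + 1] if at_start else arc[-(k + 1):]
    dy = seg[-1, 1] - seg[0, 1]
    dx = seg[-1, 0] - seg[0, 0]
    if abs(dy) < 1e-9:
        return 0.0
    return float(dx / dy)


def close_sheath(upper: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """Closed sheath boundary: upper arc + two parabolic side bridges + lower arc.

    The third parabola constraint is tangent continuity with the upper arc at
    its endpoint; if the resulting polygon self-intersects, straight-line
    bridges are used instead (flagged in the log).
    """
    upper = np.asarray(upper, float)
    lower = np.asarray(lower, float)
    if len(upper) < 2 or len(lower) < 2:
        raise ContourError("upper and lower sheath polylines need >= 2 points each")
    # upper ordered right -> left; lower ordered left -> right
    if upper[0, 0] < upper[-1, 0]:
        upper = upper[::-1]
    if lower[0, 0] > lower[-1, 0]:
        lower = lower[::-1]
    u_right, u_left = upper[0], upper[-1]
    l_left, l_right = lower[0], lower[-1]

    right = _side_parabola(u_right, _endpoint_tangent(upper, at_start=True), l_right)
    left = _side_parabola(u_left, _endpoint_tangent(upper, at_start=False), l_left)

    def assemble(right_bridge, left_bridge):
        # traverse: left->right along lower, up the right bridge, right->left
        # along upper, down the left bridge
        return np.vstack([lower, right_bridge[::-1][1:], upper[1:], left_bridge[1:-1]])

    closed = assemble(right, left)
    check = closed[:: max(1, len(closed) // 80)]
    if not polygon_is_simple(check):
        log.warning("parabolic sheath closure self-intersects; straight-line fallback")
        right = np.array([u_right, l_right])
        left = np.array([u_left, l_left])
        closed = assemble(right, left)
    return closed


def classify_boundary_group(image: np.ndarray, bottom_point) -> BoundaryGroup:
    """Clear/fuzzy label from 15x15 windows above and below the bottom point.

    Window centres sit 8 px above and below the bottom-most tendon boundary
    point; the image is labelled clear iff the upper window mean exceeds the
    lower one by strictly more than 30 intensity units.
    """
    img = np.asarray(image, float)
    x = int(round(bottom_point[0]))
    y = int(round(bottom_point[1]))
    half = GROUP_WINDOW // 2

    def window_mean(cy):
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = x - half, x + half + 1
        rr0, rr1 = max(0, r0), min(img.shape[0], r1)
        cc0, cc1 = max(0, c0), min(img.shape[1], c1)
        if (rr0, rr1, cc0, cc1) != (r0, r1, c0, c1):
            log.warning("group window clipped at the image border")
        if rr0 >= rr1 or cc0 >= cc1:
            raise ValueError("group window entirely outside the image")
        return float(img[rr0:rr1, cc0:cc1].mean())

    contrast = window_mean(y - GROUP_OFFSET) - window_mean(y + GROUP_OFFSET)
    label = "clear" if contrast > GROUP_THRESHOLD else "fuzzy"
    return BoundaryGroup(label=label, window_contrast=contrast)


# ---------------------------------------------------------------------------
# the trainable segmenter
# ---------------------------------------------------------------------------

class AtasmSegmenter(BaseEstimator):
    """Adaptive texture-based active shape model segmenter (fit/predict).

    Parameters
    ----------
    target : {"tendon", "sheath"}
        Which structure the energy terms are signed for.
    variance_retained : float
        PCA variance fraction kept by the shape model.
    ga_* : genetic-algorithm settings (population, generation cap, operator
        probabilities, convergence patience).
    max_rounds, rel_tol : alternation schedule of pose refinement vs GA.
    sad_ceiling : float or None
        Localization SAD above this flags the result low-confidence.
    random_state : int or None
        Seed for the GA.

    Attributes (after ``fit``)
    --------------------------
    shape_model_ : PointDistributionModel
    texture_model_ : TextureProfileModel
    weights_ : EnergyWeights
    template_ : IntensityTemplate (tendon target only)
    """

    def __init__(self, target: str = "tendon", variance_retained: float = 0.98,
                 ga_population: int = 50, ga_max_generations: int = 200,
                 ga_crossover: float = 0.5, ga_mutation: float = 0.01,
                 ga_patience: int = 10, max_rounds: int = 5, rel_tol: float = 1e-4,
                 sad_ceiling: float | None = None, random_state: int | None = None):
        self.target = target
        self.variance_retained = variance_retained
        self.ga_population = ga_population
        self.ga_max_generations = ga_max_generations
        self.ga_crossover = ga_crossover
        self.ga_mutation = ga_mutation
        self.ga_patience = ga_patience
        self.max_rounds = max_rounds
        self.rel_tol = rel_tol
        self.sad_ceiling = sad_ceiling
        self.random_state = random_state

    def _ga_config(self, seed: int | None) -> GAConfig:
        return GAConfig(population_size=self.ga_population,
                        crossover_prob=self.ga_crossover,
                        mutation_prob=self.ga_mutation,
                        convergence_patience=self.ga_patience,
                        max_generations=self.ga_max_generations,
                        rng_seed=seed if seed is not None else self.random_state)

    def fit(self, images, contours, y=None):
        """Train shape, texture, weight and (tendon) template models."""
        if self.target not in ("tendon", "sheath"):
            raise ValueError(f"target must be tendon|sheath, got {self.target}")
        self.shape_model_ = PointDistributionModel(
            variance_retained=self.variance_retained).fit(contours)
        self.texture_model_ = build_texture_model(images, contours)
        self.weights_ = train_weights(images, contours, self.texture_model_,
                                      target=self.target)
        if self.target == "tendon":
            self.template_ = train_template(images, contours)
        return self

    # -- initialization -------------------------------------------------
    def _initial_params(self, image, manual_box=None, init_centroid=None):
        diagnostics = {}
        if self.target == "tendon":
            if manual_box is not None:
                init = manual_roi_override(image, manual_box, self.template_)
                diagnostics["localization"] = "manual"
            else:
                origin = coarse_locate(image, self.template_)
                transform, init, final_sad = fine_locate(image, self.template_, origin)
                diagnostics.update(localization="coarse-to-fine",
                                   coarse_origin=origin, fine_transform=transform,
                                   localization_sad=final_sad)
                if self.sad_ceiling is not None and final_sad > self.sad_ceiling:
                    diagnostics["low_confidence"] = True
                    log.warning("localization SAD %.2f above ceiling %.2f",
                                final_sad, self.sad_ceiling)
            pose = pose_from_alignment(
                self.shape_model_.mean_shape_.reshape(-1, 2), init.points)
        else:
            if init_centroid is None:
                raise ValueError("sheath segmentation needs the tendon centroid")
            pose = (float(init_centroid[0]), float(init_centroid[1]),
                    self.shape_model_.mean_scale_, 0.0)
            diagnostics["localization"] = "tendon-centroid"
        params = ShapeParams(np.zeros(self.shape_model_.n_modes_), pose)
        return params, diagnostics

    # -- inference -------------------------------------------------------
    def segment_image(self, image, manual_box=None, init_centroid=None,
                      seed: int | None = None):
        """Segment one image; returns ``(Contour, diagnostics)``."""
        params, diagnostics = self._initial_params(image, manual_box, init_centroid)
        evaluator = EnergyEvaluator(image, self.texture_model_, target=self.target)
        params, opt_diag = alternate_optimize(
            evaluator, self.shape_model_, self.weights_, params,
            ga_config=self._ga_config(seed),
            max_rounds=self.max_rounds, rel_tol=self.rel_tol)
        diagnostics.update(opt_diag, pose=params.pose, b=params.b)
        contour = self.shape_model_.synthesize(params)
        return contour, diagnostics

    def predict(self, images, seed: int | None = None):
        """Segment a sequence of images; returns a list of contours."""
        return [self.segment_image(img, seed=seed)[0] for img in images]


# ---------------------------------------------------------------------------
# functional pipeline wrappers
# ---------------------------------------------------------------------------

def segment_tendon(image, segmenter: AtasmSegmenter, manual_box=None,
                   seed: int | None = None) -> SegmentationResult:
    """Full tendon segmentation with the clear/fuzzy group label."""
    contour, diagnostics = segmenter.segment_image(image, manual_box=manual_box,
                                                   seed=seed)
    bottom = contour.points[np.argmax(contour.points[:, 1])]
    group = classify_boundary_group(image, bottom)
    return SegmentationResult(tendon=contour, group=group, diagnostics=diagnostics)


def segment_sheath(image, tendon_result: SegmentationResult,
                   sheath_segmenter: AtasmSegmenter,
                   seed: int | None = None) -> SegmentationResult:
    """Sheath segmentation initialized at the tendon centroid, post-processed."""
    tendon = tendon_result.tendon
    contour, diagnostics = sheath_segmenter.segment_image(
        image, init_centroid=tendon.centroid(), seed=seed)
    lower = lower_sheath_from_tendon(tendon)
    upper = _upper_sheath_arc(contour, tendon.centroid())
    closed = close_sheath(upper, lower)
    return SegmentationResult(
        tendon=tendon, sheath=contour, sheath_upper=upper, sheath_lower=lower,
        sheath_closed=closed, group=tendon_result.group,
        diagnostics={**tendon_result.diagnostics, "sheath": diagnostics})
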