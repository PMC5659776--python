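"""Point distribution model: Procrustes alignment, PCA, synthesis, clamping.

The statistical shape model follows the classical active-shape-model
construction: training contours (20 corresponding control points each) are
brought into a common frame by generalized Procrustes analysis, the principal
components of the aligned shape vectors are extracted, and any model shape is
expressed as ``X = X_mean + P b`` followed by a similarity pose transform.
Mode weights are clamped to ``|b_i| <= 3 sqrt(lambda_i)`` so synthesized
shapes stay within three standard deviations of the training variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .contour import Contour, ContourError

_GPA_MAX_ITER = 10
_GPA_TOL = 1e-7


# ---------------------------------------------------------------------------
# pose (similarity transform) helpers
# ---------------------------------------------------------------------------

@dataclass
class ShapeParams:
    """Mode weights ``b`` plus a similarity pose (tx, ty, scale, rotation)."""

    b: np.ndarray
    pose: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(-1)

    def copy(self) -> "ShapeParams":
        return ShapeParams(self.b.copy(), tuple(self.pose))


def apply_pose(points: np.ndarray, pose) -> np.ndarray:
    """Apply a similarity transform (tx, ty, scale, rotation-rad) to points."""
    tx, ty, s, theta = pose
    c, si = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -si], [si, c]])
    return s * points @ rot.T + np.array([tx, ty])


def pose_from_alignment(src: np.ndarray, dst: np.ndarray):
    """Least-squares similarity pose mapping ``src`` points onto ``dst``.

    Closed-form (Umeyama/SVD) solution over translation, uniform scale and
    rotation.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    a = src - mu_s
    b = dst - mu_d
    cov = a.T @ b
    u, sv, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s_mat = np.diag([1.0, d])
    rot = vt.T @ s_mat @ u.T
    denom = np.sum(a * a)
    if denom == 0:
        raise ContourError("cannot align: source points are coincident")
    scale = np.trace(np.diag(sv) @ s_mat) / denom
    theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    t = mu_d - scale * (rot @ mu_s)
    return (float(t[0]), float(t[1]), float(scale), theta)


# ---------------------------------------------------------------------------
# generalized Procrustes alignment
# ---------------------------------------------------------------------------

def _align_one(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    pose = pose_from_alignment(points, target)
    return apply_pose(points, pose)


def _normalize(points: np.ndarray) -> np.ndarray:
    """Centroid to origin, root-mean-square point radius to 1."""
    out = points - points.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum(out**2, axis=1)))
    if rms == 0:
        raise ContourError("cannot normalize an all-coincident shape")
    return out / rms


def procrustes_align(shapes):
    """Generalized Procrustes analysis of corresponding-point contours.

    Iteratively aligns every shape to the running mean with a full similarity
    transform and re-estimates the mean (normalized to centroid 0, unit RMS
    scale) until the mean moves by less than 1e-7 RMS or 10 iterations.

    Returns
    -------
    aligned : list of Contour
    mean : Contour
    """
    if len(shapes) < 2:
        raise ContourError("Procrustes alignment needs at least 2 shapes")
    arrs = []
    for s in shapes:
        pts = s.points if isinstance(s, Contour) else np.asarray(s, float)
        arrs.append(pts.astype(float))
    n_pts = {len(a) for a in arrs}
    if len(n_pts) != 1:
        raise ContourError(f"shapes have inconsistent point counts: {sorted(n_pts)}")

    mean = _normalize(arrs[0])
    aligned = arrs
    for _ in range(_GPA_MAX_ITER):
        aligned = [_align_one(a, mean) for a in arrs]
        new_mean = _normalize(np.mean(aligned, axis=0))
        shift = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if shift < _GPA_TOL:
            break
    # fix the rotational gauge (otherwise the mean inherits the arbitrary
    # pose of the first input): rotate so the first landmark — the top
    # anchor by the contour convention — sits straight above the centroid
    d = mean[0]
    rot_angle = -np.pi / 2 - np.arctan2(d[1], d[0])
    mean = apply_pose(mean, (0.0, 0.0, 1.0, rot_angle))
    aligned = [_align_one(a, mean) for a in arrs]
    spacing = shapes[0].pixel_spacing_mm if isinstance(shapes[0], Contour) else None
    kwargs = {} if spacing is None else {"pixel_spacing_mm": spacing}
    return ([Contour(a, **kwargs) for a in aligned], Contour(mean, **kwargs))


# ---------------------------------------------------------------------------
# the PCA shape model
# ---------------------------------------------------------------------------

class PointDistributionModel(BaseEstimator, TransformerMixin):
    """PCA point distribution model over aligned 20-point contours.

    Parameters
    ----------
    variance_retained : float, default 0.98
        Fraction of total shape variance covered by the retained modes; the
        number of modes is additionally capped at ``n_training - 1``.
    clamp_sd : float, default 3.0
        Half-width of the per-mode clamp box in standard deviations
        (``|b_i| <= clamp_sd * sqrt(lambda_i)``).
    strict_print_clamp : bool, default False
        Use ``clamp_sd * lambda_i`` (no square root) as the clamp bound
        instead of the standard-deviation form.

    Attributes
    ----------
    mean_shape_ : (40,) ndarray
        Mean aligned shape vector (x, y interleaved).
    components_ : (40, m) ndarray
        Orthonormal shape modes (columns).
    eigenvalues_ : (m,) ndarray
        Variances of the retained modes, non-increasing.
    n_training_ : int
    mean_scale_ : float
        Mean RMS scale of the training shapes in image coordinates (used to
        initialize pose at test time).
    """

    def __init__(self, variance_retained: float = 0.98, clamp_sd: float = 3.0,
                 strict_print_clamp: bool = False):
        self.variance_retained = variance_retained
        self.clamp_sd = clamp_sd
        self.strict_print_clamp = strict_print_clamp

    # -- fitting --------------------------------------------------------
    def fit(self, shapes, y=None):
        """Align the training contours and extract the PCA modes."""
        if len(shapes) < 2:
            raise ContourError("PCA shape model needs at least 2 training shapes")
        aligned, mean = procrustes_align(shapes)
        vecs = np.stack([c.as_vector() for c in aligned])
        mu = vecs.mean(axis=0)
        centered = vecs - mu
        cov = centered.T @ centered / len(vecs)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]

        total = float(evals.sum())
        # absolute guard: identical training shapes give numerically-zero
        # variance that must not be promoted to a retained mode
        if total <= 1e-12 * float(np.sum(mu**2) + 1.0):
            m = 0
        else:
            frac = np.cumsum(evals) / total
            m = int(np.searchsorted(frac, self.variance_retained) + 1)
            m = min(m, len(shapes) - 1, int(np.sum(evals > 1e-12 * total)))
        self.mean_shape_ = mu
        self.components_ = evecs[:, :m]
        self.eigenvalues_ = evals[:m]
        self.all_eigenvalues_ = evals
        self.n_training_ = len(shapes)
        self.aligned_ = aligned
        self.mean_contour_ = mean
        scales = []
        for s in shapes:
            pts = s.points if isinstance(s, Contour) else np.asarray(s, float)
            pts = pts - pts.mean(axis=0)
            scales.append(np.sqrt(np.mean(np.sum(pts**2, axis=1))))
        self.mean_scale_ = float(np.mean(scales))
        self.pixel_spacing_mm_ = (
            shapes[0].pixel_spacing_mm if isinstance(shapes[0], Contour) else 0.075
        )
        return self

    @property
    def n_modes_(self) -> int:
        return self.components_.shape[1]

    # -- clamping -------------------------------------------------------
    def clamp_bounds(self) -> np.ndarray:
        """Per-mode half-widths of the allowed box for ``b``."""
        lam = self.eigenvalues_
        if self.strict_print_clamp:
            return self.clamp_sd * lam
        return self.clamp_sd * np.sqrt(lam)

    def clamp_params(self, params: ShapeParams) -> ShapeParams:
        """Clip every mode weight into its clamp box (zero-variance modes to 0)."""
        bound = self.clamp_bounds()
        b = np.clip(params.b, -bound, bound)
        return ShapeParams(b, params.pose)

    # -- synthesis / projection ----------------------------------------
    def synthesize(self, params: ShapeParams) -> Contour:
        """Shape vector ``X_mean + P b`` mapped through the pose transform.

        Out-of-bound mode weights are clamped first; out-of-model shapes are
        never produced silently.
        """
        params = self.clamp_params(params)
        if len(params.b) != self.n_modes_:
            raise ContourError(
                f"expected {self.n_modes_} mode weights, got {len(params.b)}"
            )
        vec = self.mean_shape_ + self.components_ @ params.b
        pts = vec.reshape(-1, 2)
        return Contour(apply_pose(pts, params.pose),
                       pixel_spacing_mm=self.pixel_spacing_mm_)

    def synthesize_batch(self, b_matrix: np.ndarray, pose) -> np.ndarray:
        """Vectorized synthesis of many shapes sharing one pose.

        Parameters
        ----------
        b_matrix : (n, m) array of mode weights (assumed already clamped).
        pose : (tx, ty, scale, rotation)

        Returns
        -------
        (n, n_points, 2) array of contour points.
        """
        vecs = self.mean_shape_[None, :] + b_matrix @ self.components_.T
        pts = vecs.reshape(len(b_matrix), -1, 2)
        tx, ty, s, theta = pose
        c, si = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -si], [si, c]])
        return s * pts @ rot.T + np.array([tx, ty])

    def project(self, contour: Contour) -> ShapeParams:
        """Best-fit pose and mode weights for an arbitrary contour."""
        pose = pose_from_alignment(self.mean_shape_.reshape(-1, 2), contour.points)
        tx, ty, s, theta = pose
        # invert the pose to express the contour in model frame
        c, si = np.cos(-theta), np.sin(-theta)
        rot = np.array([[c, -si], [si, c]])
        model_pts = (contour.points - np.array([tx, ty])) @ rot.T / s
        b = self.components_.T @ (model_pts.reshape(-1) - self.mean_shape_)
        return ShapeParams(b, pose)

    # -- sklearn transformer surface ------------------------------------
    def transform(self, shapes):
        """Mode-weight vectors (n_shapes, n_modes) of the given contours."""
        return np.stack([self.project(c).b for c in shapes])

    def inverse_transform(self, B):
        """Contours synthesized from mode-weight rows at identity pose."""
        return [self.synthesize(ShapeParams(b)) for b in np.atleast_2d(B)]


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_pca(aligned_or_raw_shapes, variance_retained: float = 0.98) -> PointDistributionModel:
    """Fit a :class:`PointDistributionModel` on a list of contours."""
    return PointDistributionModel(variance_retained=variance_retained).fit(
        aligned_or_raw_shapes
    )


def synthesize_shape(model: PointDistributionModel, params: ShapeParams) -> Contour:
    return model.synthesize(params)


def clamp_params(params: ShapeParams, model: PointDistributionModel) -> ShapeParams:
    return model.clamp_params(params)
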