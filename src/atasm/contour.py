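"""Closed contours of 20 control points: the shape unit of the whole system.

Coordinates are 0-based with ``x`` = column and ``y`` = row (row increases
downward).  Contours are stored counter-clockwise (positive shoelace area in
the (x, y) frame, i.e. top -> right -> bottom -> left when viewed on screen)
starting at the topmost anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CONTROL_POINTS = 20
#: points inserted between each adjacent pair of the 4 extremal anchors
_N_BETWEEN = 4
DEFAULT_PIXEL_SPACING_MM = 0.075


class ContourError(ValueError):
    """Raised for degenerate or malformed contour inputs."""


@dataclass
class Contour:
    """Ordered closed polyline in image pixel coordinates.

    Parameters
    ----------
    points : (n, 2) float array
        Vertex coordinates as ``(x, y)`` pairs; sub-pixel values allowed.
    closed : bool
        Whether the last vertex connects back to the first (always true for
        tendon and sheath contours).
    pixel_spacing_mm : float
        Physical size of one pixel side, carried as metadata.
    """

    points: np.ndarray
    closed: bool = True
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ContourError(
                f"contour points must be (n, 2); got {self.points.shape}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def signed_area(self) -> float:
        """Shoelace area in the (x, y) frame; positive for CCW ordering."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def as_vector(self) -> np.ndarray:
        """Flatten to the interleaved (x0, y0, x1, y1, ...) shape vector."""
        return self.points.reshape(-1)

    @classmethod
    def from_vector(cls, vec: np.ndarray, **kwargs) -> "Contour":
        return cls(np.asarray(vec, dtype=float).reshape(-1, 2), **kwargs)

    def copy(self) -> "Contour":
        return Contour(self.points.copy(), self.closed, self.pixel_spacing_mm)


def polygon_is_simple(points: np.ndarray) -> bool:
    """True when no two non-adjacent edges of the closed polygon intersect."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        return False
    a = pts
    b = np.roll(pts, -1, axis=0)

    def _cross(p, q, r):
        # orientation of r relative to segment p->q, broadcast over pairs
        return ((r[..., 1] - p[..., 1]) * (q[..., 0] - p[..., 0])
                - (q[..., 1] - p[..., 1]) * (r[..., 0] - p[..., 0]))

    p1 = a[:, None, :]
    p2 = b[:, None, :]
    p3 = a[None, :, :]
    p4 = b[None, :, :]
    d1 = _cross(p3, p4, p1)
    d2 = _cross(p3, p4, p2)
    d3 = _cross(p1, p2, p3)
    d4 = _cross(p1, p2, p4)
    crossing = ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0))
    i = np.arange(n)
    adjacent = (np.abs(i[:, None] - i[None, :]) <= 1) | \
               (np.abs(i[:, None] - i[None, :]) == n - 1)
    return not bool(np.any(crossing & ~adjacent))


def densify(points: np.ndarray, step: float = 1.0, closed: bool = True) -> np.ndarray:
    """Resample a polyline at roughly ``step``-pixel arc increments.

    The original vertices are retained; each edge is subdivided uniformly so
    no segment exceeds ``step``.
    """
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        d = float(np.hypot(*(b - a)))
        n = max(1, int(np.ceil(d / step)))
        t = np.arange(n) / n
        out.append(a[None, :] + t[:, None] * (b - a)[None, :])
    out.append(pts[-1:])
    dense = np.vstack(out)
    if closed:
        dense = dense[:-1]
    return dense


def arc_lengths(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """Cumulative arc length at each vertex (starting at 0)."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if closed:
        seg = np.append(seg, np.linalg.norm(pts[0] - pts[-1]))
    return np.concatenate([[0.0], np.cumsum(seg)])


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return points in counter-clockwise (positive shoelace) order."""
    c = Contour(points)
    if c.signed_area() < 0:
        return points[::-1].copy()
    return points


def _anchor_indices(pts: np.ndarray) -> np.ndarray:
    """Indices of the topmost, rightmost, bottommost and leftmost vertices.

    Ties are broken toward the smaller companion coordinate for determinism.
    """
    x, y = pts[:, 0], pts[:, 1]

    def _argext(primary, secondary):
        best = np.flatnonzero(primary == primary.min())
        return int(best[np.argmin(secondary[best])])

    top = _argext(y, x)
    bottom = _argext(-y, x)
    left = _argext(x, y)
    right = _argext(-x, y)
    return np.array([top, right, bottom, left])


def resample_contour(raw_points, pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM) -> Contour:
    """Resample a raw closed outline to the 20-point control representation.

    The four extremal vertices (topmost, rightmost, bottommost, leftmost) act
    as anchors; four points are placed at equal arc-length fractions between
    each adjacent anchor pair.  Output is counter-clockwise starting at the
    top anchor.

    Raises
    ------
    ContourError
        If the input has fewer than 8 points, encloses (numerically) zero
        area, has duplicate anchors, or self-intersects.
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContourError(f"raw points must be (n, 2); got {pts.shape}")
    # drop an explicit closing repeat of the first vertex
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 8:
        raise ContourError(f"need >= 8 points for a closed outline, got {len(pts)}")
    area = Contour(pts).signed_area()
    span = float(np.ptp(pts, axis=0).max())
    if abs(area) < 1e-9 * max(span, 1.0) ** 2 or span == 0.0:
        raise ContourError("degenerate outline: enclosed area is zero")
    if not polygon_is_simple(pts):
        raise ContourError("outline self-intersects")
    pts = ensure_ccw(pts)

    # dense resampling makes arc-length positions sub-pixel accurate even for
    # sparse raw outlines
    dense = densify(pts, step=0.25, closed=True)
    anchors = _anchor_indices(dense)
    if len(np.unique(anchors)) < 4:
        raise ContourError("degenerate outline: duplicate extremal anchors")

    s = arc_lengths(dense, closed=True)
    total = s[-1]
    # order anchors along the CCW traversal, starting from the topmost one
    anchors = anchors[np.argsort(s[anchors])]
    start = int(np.argmin(dense[anchors][:, 1]))
    anchors = np.roll(anchors, -start)

    out = []
    n_seg = len(anchors)
    for k in range(n_seg):
        i0, i1 = anchors[k], anchors[(k + 1) % n_seg]
        s0 = s[i0]
        s1 = s[i1]
        if s1 <= s0:  # segment wraps past the traversal origin
            s1 += total
        out.append(dense[i0])
        fracs = (np.arange(1, _N_BETWEEN + 1)) / (_N_BETWEEN + 1)
        for f in fracs:
            target = (s0 + f * (s1 - s0)) % total
            out.append(_point_at_arclength(dense, s, target))
    points = np.asarray(out)
    assert len(points) == N_CONTROL_POINTS
    return Contour(points, closed=True, pixel_spacing_mm=pixel_spacing_mm)


def _point_at_arclength(dense: np.ndarray, s: np.ndarray, target: float) -> np.ndarray:
    """Linear interpolation of the dense closed polyline at arc length target."""
    n = len(dense)
    j = int(np.searchsorted(s, target, side="right")) - 1
    j = min(max(j, 0), len(s) - 2)
    seg = s[j + 1] - s[j]
    t = 0.0 if seg == 0 else (target - s[j]) / seg
    a = dense[j % n]
    b = dense[(j + 1) % n]
    return a + t * (b - a)


def outward_normals(contour: Contour) -> np.ndarray:
    """Unit outward normal at each control point.

    The tangent at point ``i`` is estimated from its two neighbours,
    ``c(i+1) - c(i-1)``; the normal is its perpendicular with the sign chosen
    to point away from the contour centroid (stable under noise, and the
    centroid disambiguates orientation).
    """
    pts = contour.points
    tan = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    nrm = np.stack([tan[:, 1], -tan[:, 0]], axis=1)
    lengths = np.linalg.norm(nrm, axis=1, keepdims=True)
    lengths[lengths == 0] = 1.0
    nrm = nrm / lengths
    away = pts - contour.centroid()
    flip = np.sum(nrm * away, axis=1) < 0
    nrm[flip] *= -1
    return nrm
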