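"""Gabor and Laws texture images and contour-normal texture profiles.

Two texture features drive the segmentation energy: the imaginary part of a
0-degree Gabor filter response (sensitive to horizontal intensity transitions
such as the upper/lower tendon boundary) and the Laws E5L5 level-edge energy
image.  Along the contour, each of the 20 control points contributes 5
samples taken every 2 px on its normal (two inside, two outside, one on the
contour), giving a 100-element texture profile per feature.  Averaging the
training profiles yields the texture model that the energy terms compare
against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contour import Contour, outward_normals

log = logging.getLogger(__name__)

#: normal offsets in px; negative = inside the contour
PROFILE_OFFSETS = np.array([-4.0, -2.0, 0.0, 2.0, 4.0])

GABOR_SIGMA = 4.0        # px, kernel envelope width (not stated upstream; decided)
GABOR_PHI = 0.1          # cycles/px carrier frequency
GABOR_SIZE = 25          # odd kernel side
GABOR_ANGLES_DEG = (0.0, 30.0, 60.0, 90.0)

FEATURE_GABOR = "gabor_imag_0deg"
FEATURE_LAWS = "laws_E5L5"
ENERGY_FEATURES = (FEATURE_GABOR, FEATURE_LAWS)


@dataclass
class TextureImage:
    """A per-pixel texture response with the extent of its source image."""

    values: np.ndarray
    feature_name: str


@dataclass
class TextureProfile:
    """100-vector of texture samples: 20 control points x 5 normal offsets.

    Ordering is point-major: the 5 samples of control point 0 come first.
    """

    values: np.ndarray
    feature_name: str
    sample_offsets: np.ndarray = field(default_factory=lambda: PROFILE_OFFSETS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) != 100:
            raise ValueError(f"texture profile must have 100 values, got {len(self.values)}")


@dataclass
class TextureProfileModel:
    """Per-feature mean 100-element profiles averaged over training images."""

    mean_profiles: dict
    n_training: int

    def __post_init__(self) -> None:
        for name, vec in self.mean_profiles.items():
            vec = np.asarray(vec, dtype=float).reshape(-1)
            if len(vec) != 100:
                raise ValueError(f"profile '{name}' must have 100 values")
            self.mean_profiles[name] = vec


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def gabor_kernel(sigma: float = GABOR_SIGMA, phi: float = GABOR_PHI,
                 theta: float = 0.0, size: int = GABOR_SIZE):
    """Real and imaginary Gabor kernels on an integer grid centred at 0.

    ``G(x, y) = 1/(2 pi sigma^2) exp(-(x^2+y^2)/(2 sigma^2))
    {cos | sin}[2 pi phi (x cos theta + y sin theta)]``

    Returns ``(real, imag)`` arrays of shape ``(size, size)``.
    """
    if size % 2 == 0:
        raise ValueError(f"Gabor kernel size must be odd, got {size}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    envelope = np.exp(-(x**2 + y**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    carrier = 2 * np.pi * phi * (x * np.cos(theta) + y * np.sin(theta))
    return envelope * np.cos(carrier), envelope * np.sin(carrier)


def laws_kernel() -> np.ndarray:
    """The 5x5 Laws level-edge (E5 x L5) kernel.

    Outer product of the edge detector E5 = (-1, -2, 0, 2, 1)^T with the
    local-average mask L5 = (1, 4, 6, 4, 1).
    """
    e5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
    l5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    return np.outer(e5, l5)


# ---------------------------------------------------------------------------
# texture images
# ---------------------------------------------------------------------------

def gabor_texture_image(image: np.ndarray, theta_deg: float = 0.0,
                        sigma: float = GABOR_SIGMA, phi: float = GABOR_PHI,
                        size: int = GABOR_SIZE) -> TextureImage:
    """Imaginary-part Gabor response (same extent, reflected border).

    The 0-degree response is the feature used by the segmentation energy;
    other angles are available for inspection.
    """
    _, imag = gabor_kernel(sigma=sigma, phi=phi, theta=np.deg2rad(theta_deg), size=size)
    values = ndimage.convolve(np.asarray(image, float), imag, mode="reflect")
    name = FEATURE_GABOR if theta_deg == 0.0 else f"gabor_imag_{int(theta_deg)}deg"
    return TextureImage(values=values, feature_name=name)


def laws_texture_image(image: np.ndarray) -> TextureImage:
    """Laws E5L5 level-edge response (same extent, reflected border)."""
    values = ndimage.convolve(np.asarray(image, float), laws_kernel(), mode="reflect")
    return TextureImage(values=values, feature_name=FEATURE_LAWS)


def energy_texture_images(image: np.ndarray) -> dict:
    """The two texture images consumed by the energy function."""
    return {
        FEATURE_GABOR: gabor_texture_image(image),
        FEATURE_LAWS: laws_texture_image(image),
    }


# ---------------------------------------------------------------------------
# profile sampling
# ---------------------------------------------------------------------------

def bilinear_sample(values: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``values`` at (x, y) positions.

    Positions outside the image take the nearest border value.
    """
    xy = np.asarray(xy, float)
    flat = xy.reshape(-1, 2)
    h, w = values.shape
    if np.any(flat[:, 0] < 0) or np.any(flat[:, 0] > w - 1) or \
       np.any(flat[:, 1] < 0) or np.any(flat[:, 1] > h - 1):
        log.warning("sample positions outside image; nearest-border values used")
    coords = np.stack([flat[:, 1], flat[:, 0]])  # map_coordinates wants (row, col)
    out = ndimage.map_coordinates(np.asarray(values, float), coords,
                                  order=1, mode="nearest")
    return out.reshape(xy.shape[:-1])


def profile_sample_points(contour: Contour,
                          offsets: np.ndarray = PROFILE_OFFSETS) -> np.ndarray:
    """(n_points, n_offsets, 2) sampling positions along outward normals."""
    normals = outward_normals(contour)
    return (contour.points[:, None, :]
            + offsets[None, :, None] * normals[:, None, :])


def sample_profile(texture: TextureImage, contour: Contour,
                   offsets: np.ndarray = PROFILE_OFFSETS) -> TextureProfile:
    """Texture profile of a contour on one texture image.

    For every control point, 5 samples are taken at offsets (-4, -2, 0, +2,
    +4) px along the outward normal (negative = inside) with bilinear
    interpolation, and concatenated point-major into a 100-vector.
    """
    pts = profile_sample_points(contour, offsets)
    samples = bilinear_sample(texture.values, pts)
    return TextureProfile(values=samples.reshape(-1),
                          feature_name=texture.feature_name,
                          sample_offsets=np.asarray(offsets, float))


def build_texture_model(images, contours) -> TextureProfileModel:
    """Element-wise mean of training texture profiles, per feature."""
    if len(images) != len(contours) or len(images) < 1:
        raise ValueError("need equal, nonzero numbers of training images and contours")
    acc = {name: [] for name in ENERGY_FEATURES}
    for image, contour in zip(images, contours):
        for name, tex in energy_texture_images(image).items():
            acc[name].append(sample_profile(tex, contour).values)
    mean_profiles = {name: np.mean(vals, axis=0) for name, vals in acc.items()}
    return TextureProfileModel(mean_profiles=mean_profiles, n_training=len(images))
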