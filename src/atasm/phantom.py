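"""Seeded synthetic ultrasound phantoms with known ground truth.

The phantom emulates the transverse A1-pulley anatomy: a hyperechoic
(bright) elliptical tendon, a hypoechoic (dark) synovial-fluid band
surrounding it, a bright volar-plate band beneath, and multiplicative
speckle.  The bottom tendon boundary contrast is controllable so phantoms
fall into the same clear/fuzzy grouping used for real scans.  Tendon shape
varies through a 2-mode truncated Fourier perturbation of the ellipse
radius, giving the PCA shape model a known low-dimensional truth to recover.

The speckle field is a unit-mean, lightly smoothed Rayleigh field blended
multiplicatively: ``I -> I * ((1 - s) + s * R)`` with blend amplitude ``s``
(default 0.25).  This is a test surrogate for ultrasound speckle, not a
beam-forming simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from .contour import Contour, resample_contour

#: dense angular sampling of phantom boundaries
_N_THETA = 720


@dataclass
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic phantom."""

    image_shape: tuple[int, int] = (224, 288)           # (rows, cols)
    tendon_center: tuple[float, float] = (144.0, 100.0)  # (x, y)
    tendon_axes: tuple[float, float] = (42.0, 27.0)     # semi-axes (a, b) px
    tendon_rotation: float = 0.0                        # radians
    sheath_width: float = 11.0                          # px band width
    tendon_intensity: float = 155.0
    sheath_intensity: float = 55.0
    background_intensity: float = 90.0
    plate_intensity: float = 190.0
    plate_thickness: float = 12.0
    bottom_contrast: str = "clear"                      # {"clear", "fuzzy"}
    fuzzy_step: float = 20.0                            # tendon-to-band step in fuzzy mode
    speckle_strength: float = 0.25                      # multiplicative blend amplitude
    perturb_amplitudes: tuple[float, float] = (0.05, 0.05)  # std of the 2 radius modes
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.bottom_contrast not in ("clear", "fuzzy"):
            raise ValueError(f"bottom_contrast must be clear|fuzzy, got {self.bottom_contrast}")
        for v in (self.tendon_intensity, self.sheath_intensity,
                  self.background_intensity, self.plate_intensity):
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"intensity {v} outside [0, 255]")
        h, w = self.image_shape
        cx, cy = self.tendon_center
        a, b = self.tendon_axes
        # generous bound on the outermost sheath radius incl. perturbation
        r_max = max(a, b) * (1 + 3 * sum(self.perturb_amplitudes)) + self.sheath_width
        margin = 12.0
        if (cx - r_max < margin or cx + r_max > w - margin
                or cy - r_max < margin
                or cy + r_max + 2 + self.plate_thickness > h - margin):
            raise ValueError("tendon+sheath+plate must fit in the image with >= 12 px margin")


def _boundary(spec: PhantomSpec, mode_coeffs, extra_radius: float = 0.0) -> np.ndarray:
    """Dense (x, y) boundary of the perturbed ellipse (+ optional offset)."""
    theta = np.linspace(0.0, 2 * np.pi, _N_THETA, endpoint=False)
    a, b = spec.tendon_axes
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    c2, c3 = mode_coeffs
    r = r_ell * (1.0 + c2 * np.cos(2 * theta) + c3 * np.sin(3 * theta)) + extra_radius
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    rot = spec.tendon_rotation
    if rot:
        xr = x * np.cos(rot) - y * np.sin(rot)
        y = x * np.sin(rot) + y * np.cos(rot)
        x = xr
    cx, cy = spec.tendon_center
    return np.stack([x + cx, y + cy], axis=1)


def _fill(shape, boundary_xy) -> np.ndarray:
    return polygon2mask(shape, boundary_xy[:, ::-1])


def speckle_field(shape, rng: np.random.Generator, smooth_sigma: float = 1.0) -> np.ndarray:
    """Unit-mean smoothed Rayleigh field."""
    f = rng.rayleigh(scale=1.0, size=shape)
    f = ndimage.gaussian_filter(f, smooth_sigma)
    return f / f.mean()


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns
    -------
    image : (h, w) float array in [0, 255]
    truth : dict with "tendon" and "sheath" 20-point :class:`Contour` objects
        (sheath = outer boundary of the synovial-fluid band)
    group : str, "clear" or "fuzzy"
    """
    rng = np.random.default_rng(spec.rng_seed)
    amps = spec.perturb_amplitudes
    coeffs = (amps[0] * rng.standard_normal(), amps[1] * rng.standard_normal())

    tendon_xy = _boundary(spec, coeffs)
    sheath_xy = _boundary(spec, coeffs, extra_radius=spec.sheath_width)
    shape = spec.image_shape
    img = np.full(shape, spec.background_intensity, dtype=float)

    sheath_mask = _fill(shape, sheath_xy)
    tendon_mask = _fill(shape, tendon_xy)
    img[sheath_mask] = spec.sheath_intensity
    img[tendon_mask] = spec.tendon_intensity

    # bright volar plate below the sheath
    cx, cy = spec.tendon_center
    sheath_bottom = sheath_xy[:, 1].max()
    r0 = int(np.ceil(sheath_bottom)) + 2
    r1 = min(shape[0], r0 + int(spec.plate_thickness))
    c0 = max(0, int(cx - 70))
    c1 = min(shape[1], int(cx + 70))
    img[r0:r1, c0:c1] = spec.plate_intensity

    if spec.bottom_contrast == "fuzzy":
        # brighten the fluid band in a wedge below the tendon and smooth a
        # strip across the bottom boundary so the step falls below the
        # clear/fuzzy threshold
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        ang = np.arctan2(xx - cx, yy - cy)  # 0 = straight down
        wedge = sheath_mask & ~tendon_mask & (np.abs(ang) < np.deg2rad(60)) & (yy > cy)
        img[wedge] = spec.tendon_intensity - spec.fuzzy_step
        tb = tendon_xy[:, 1].max()
        s0 = max(0, int(tb - 14))
        s1 = min(shape[0], int(tb + 14))
        strip = ndimage.gaussian_filter(img[s0:s1], 2.0)
        img[s0:s1] = strip

    s = spec.speckle_strength
    if s > 0:
        img = img * ((1.0 - s) + s * speckle_field(shape, rng))
    img = np.clip(img, 0.0, 255.0)

    truth = {
        "tendon": resample_contour(tendon_xy),
        "sheath": resample_contour(sheath_xy),
    }
    return img, truth, spec.bottom_contrast


def generate_training_set(n: int, base_spec: PhantomSpec | None = None,
                          seed: int | None = None):
    """``n`` phantoms with independently seeded shape perturbations.

    Per-image tendon shapes are drawn from the 2-mode radius generator with
    the amplitudes stated in the spec, so the fitted PCA has a known
    2-dimensional truth.
    """
    if n < 2:
        raise ValueError("training set needs n >= 2")
    base_spec = base_spec or PhantomSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    out = []
    for i in range(n):
        spec = replace(base_spec, rng_seed=int(seeds[i]))
        image, truth, group = generate_phantom(spec)
        out.append((image, truth, group))
    return out


@dataclass
class PhantomPair:
    """One left/right-hand phantom pair for the classification cohort."""

    left_image: np.ndarray
    right_image: np.ndarray
    left_truth: dict
    right_truth: dict
    label: str                      # {"symptomatic", "asymptomatic"}
    affected_side: str | None      # "left"/"right" for symptomatic pairs


def generate_pair_cohort(n_pairs: int, effect_area: float = 0.30,
                         effect_speckle: float = 1.5,
                         base_spec: PhantomSpec | None = None,
                         seed: int | None = None):
    """Paired-hand cohort with a planted symptomatic effect.

    In symptomatic pairs one hand's tendon is rendered with its area enlarged
    by ``effect_area`` (semi-axes scaled by ``sqrt(1 + effect_area)``) and
    its speckle blend amplitude multiplied by ``effect_speckle`` — a
    surrogate for the thickened, hypoechoic tendon of trigger finger.
    Asymptomatic pairs are two matched normal hands.  Half the pairs are
    symptomatic, half asymptomatic.
    """
    if n_pairs < 4:
        raise ValueError("cohort needs n_pairs >= 4")
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    pairs = []
    for idx in range(n_pairs):
        label = "symptomatic" if idx < (n_pairs + 1) // 2 else "asymptomatic"
        # mild per-subject anatomy jitter, shared by both hands (bounded so
        # the enlarged symptomatic tendon always fits the canvas)
        jitter = 1.0 + float(np.clip(0.05 * rng.standard_normal(), -0.1, 0.1))
        a = base_spec.tendon_axes[0] * jitter
        b = base_spec.tendon_axes[1] * jitter
        subj = replace(base_spec, tendon_axes=(a, b))
        specs = {"left": subj, "right": subj}
        affected = None
        if label == "symptomatic":
            affected = "left" if rng.random() < 0.5 else "right"
            grow = float(np.sqrt(1.0 + effect_area))
            specs[affected] = replace(
                subj,
                tendon_axes=(a * grow, b * grow),
                speckle_strength=min(1.0, subj.speckle_strength * effect_speckle),
            )
        rendered = {}
        for side in ("left", "right"):
            spec = replace(specs[side], rng_seed=int(rng.integers(2**31)))
            image, truth, _ = generate_phantom(spec)
            rendered[side] = (image, truth)
        pairs.append(PhantomPair(
            left_image=rendered["left"][0], right_image=rendered["right"][0],
            left_truth=rendered["left"][1], right_truth=rendered["right"][1],
            label=label, affected_side=affected,
        ))
    return pairs
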