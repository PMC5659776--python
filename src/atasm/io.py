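"""Image, contour and model-archive readers/writers, plus run configuration.

Contour files follow the plain-text dialect of the expert annotations: one
point per row, ``X,Y`` (``(X,Y)`` and whitespace-separated variants are
accepted on read).  Trained models are persisted in a single versioned
``.npz`` archive bundling the shape model, texture model, adaptive weights
and (tendon) intensity template.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .contour import Contour, ContourError, DEFAULT_PIXEL_SPACING_MM
from .localization import IntensityTemplate
from .energy import EnergyWeights
from .pipeline import AtasmSegmenter
from .shape_model import PointDistributionModel
from .texture import TextureProfileModel

log = logging.getLogger(__name__)

ARCHIVE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path, pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM):
    """Read a grayscale image scaled to [0, 255].

    8-bit images pass through losslessly; 16-bit inputs are rescaled by
    their maximum; RGB inputs are converted by luminance (logged).

    Returns ``(image, metadata)`` with the pixel spacing attached.
    """
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode in ("RGB", "RGBA"):
                log.info("converting %s from %s by luminance", path, mode)
                arr = np.asarray(im.convert("L"), dtype=float)
            elif mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=float)
                if arr.max() > 0:
                    arr = arr / arr.max() * 255.0
            elif mode == "L":
                arr = np.asarray(im, dtype=float)
            else:
                arr = np.asarray(im.convert("L"), dtype=float)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return arr, {"pixel_spacing_mm": pixel_spacing_mm, "source": str(path)}


def write_image(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, float), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# contour files
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\(?\s*(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*[,\s]\s*"
                     r"(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*\)?$")


def read_contour(path, pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM) -> Contour:
    """Parse a contour text file: one ``X,Y`` pair per row.

    Accepts ``X,Y``, ``(X,Y)`` and whitespace-separated rows; raises with
    the offending line number on malformed input.
    """
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = _ROW_RE.match(line)
            if not m:
                raise ContourError(f"{path}:{lineno}: cannot parse point '{line}'")
            points.append((float(m.group(1)), float(m.group(2))))
    if len(points) < 3:
        raise ContourError(f"{path}: need >= 3 points, got {len(points)}")
    return Contour(np.asarray(points), pixel_spacing_mm=pixel_spacing_mm)


def write_contour(path, contour: Contour) -> None:
    """Write one ``X,Y`` row per point (read/write round trips exactly)."""
    with open(path, "w") as fh:
        for x, y in contour.points:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def save_model(path, segmenter: AtasmSegmenter) -> None:
    """Persist a fitted segmenter to a single versioned .npz archive."""
    sm = segmenter.shape_model_
    data = {
        "schema_version": np.array(ARCHIVE_SCHEMA_VERSION),
        "target": np.array(segmenter.target),
        "params_json": np.array(json.dumps(segmenter.get_params())),
        "shape_mean": sm.mean_shape_,
        "shape_components": sm.components_,
        "shape_eigenvalues": sm.eigenvalues_,
        "shape_mean_scale": np.array(sm.mean_scale_),
        "shape_n_training": np.array(sm.n_training_),
        "weights": segmenter.weights_.weights,
        "texture_n_training": np.array(segmenter.texture_model_.n_training),
    }
    for name, vec in segmenter.texture_model_.mean_profiles.items():
        data[f"texture_profile__{name}"] = vec
    if getattr(segmenter, "template_", None) is not None:
        data["template_pixels"] = segmenter.template_.pixels
        data["template_contour"] = segmenter.template_.reference_contour.points
        data["template_n_training"] = np.array(segmenter.template_.n_training)
    np.savez(path, **data)


def load_model(path) -> AtasmSegmenter:
    """Rebuild a fitted :class:`AtasmSegmenter` from its archive."""
    with np.load(path, allow_pickle=False) as z:
        version = int(z["schema_version"])
        if version != ARCHIVE_SCHEMA_VERSION:
            raise ValueError(f"unsupported model archive version {version}")
        params = json.loads(str(z["params_json"]))
        seg = AtasmSegmenter(**params)
        sm = PointDistributionModel(variance_retained=seg.variance_retained)
        sm.mean_shape_ = z["shape_mean"]
        sm.components_ = z["shape_components"]
        sm.eigenvalues_ = z["shape_eigenvalues"]
        sm.all_eigenvalues_ = z["shape_eigenvalues"]
        sm.mean_scale_ = float(z["shape_mean_scale"])
        sm.n_training_ = int(z["shape_n_training"])
        sm.pixel_spacing_mm_ = DEFAULT_PIXEL_SPACING_MM
        seg.shape_model_ = sm
        profiles = {}
        for key in z.files:
            if key.startswith("texture_profile__"):
                profiles[key.removeprefix("texture_profile__")] = z[key]
        seg.texture_model_ = TextureProfileModel(
            mean_profiles=profiles, n_training=int(z["texture_n_training"]))
        seg.weights_ = EnergyWeights(z["weights"], target=seg.target)
        if "template_pixels" in z.files:
            seg.template_ = IntensityTemplate(
                pixels=z["template_pixels"],
                reference_contour=Contour(z["template_contour"]),
                n_training=int(z["template_n_training"]))
    return seg


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable defaults in one place, loadable from JSON.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults; the effective configuration is echoed into every provenance
    record.
    """

    target: str = "tendon"
    variance_retained: float = 0.98          # PCA variance fraction (decided)
    ga_population: int = 50                  # decided
    ga_max_generations: int = 200            # decided
    ga_crossover: float = 0.5                # crossover probability
    ga_mutation: float = 0.01                # mutation probability
    ga_patience: int = 10                    # generations without elite change
    gabor_sigma: float = 4.0                 # decided
    gabor_phi: float = 0.1                   # decided
    search_half_width: int = 10              # weight-training line half extent (decided)
    group_threshold: float = 30.0            # clear/fuzzy intensity step
    lower_arc_deg: float = 30.0              # lower-sheath angular rule
    svm_C: float = 1.0                       # decided
    n_selected_features: int = 20
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
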