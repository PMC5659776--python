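"""Symptomatic vs asymptomatic (trigger-finger) pair classification.

From each hand's image a 41x21-px patch at the centre of the segmented
tendon is described by stationary-wavelet-transform (SWT) and wavelet-packet
(WP) subband statistics over four bases (haar, db4, db6, coif1), 12 Haralick
co-occurrence features in four directions, and the tendon / inside-sheath
areas.  Left/right feature differences per subject are ranked by the
divergence value

    D(f) = (sigma_n - sigma_a)^2 (1 + sigma_n + sigma_a)^2 / (sigma_n sigma_a),

where the sigmas are the class standard deviations of feature ``f``; the top
20 features feed an RBF support vector machine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from skimage.feature import graycomatrix
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .contour import Contour
from .metrics import ConfusionMatrix, accuracy, precision

log = logging.getLogger(__name__)

ROI_SHAPE = (21, 41)  # rows, cols
WAVELET_BASES = {"haar": "haar", "db4": "db4", "db6": "db6", "coif": "coif1"}
GLCM_LEVELS = 32
GLCM_ANGLES_DEG = (0, 45, 90, 135)
POSITIVE_LABEL = "symptomatic"

HARALICK_NAMES = (
    "angular second moment", "contrast", "correlation",
    "sum of squares variance", "inverse difference moment", "sum average",
    "sum variance", "sum entropy", "entropy", "difference variance",
    "difference entropy", "information measure of correlation",
)


# ---------------------------------------------------------------------------
# ROI and feature extraction
# ---------------------------------------------------------------------------

def extract_roi(image: np.ndarray, tendon: Contour) -> np.ndarray:
    """41x21 patch centred at the rounded tendon centroid (clipped + logged)."""
    img = np.asarray(image, float)
    cx, cy = np.round(tendon.centroid()).astype(int)
    h, w = img.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"tendon centroid ({cx}, {cy}) outside image {w}x{h}")
    rh, rw = ROI_SHAPE
    r0, c0 = cy - rh // 2, cx - rw // 2
    r1, c1 = r0 + rh, c0 + rw
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        log.warning("ROI clipped at the image border")
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(h, r1), min(w, c1)
    return img[r0:r1, c0:c1]


def _pad_dyadic(patch: np.ndarray, multiple: int = 4) -> np.ndarray:
    """Reflect-pad so both sides are divisible by ``multiple`` (2 SWT levels)."""
    h, w = patch.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    return np.pad(patch, ((0, ph), (0, pw)), mode="reflect")


_SUBBAND_LETTER = {"a": "A", "h": "Dh", "v": "Dv", "d": "Dd"}


def wavelet_features(patch: np.ndarray) -> dict:
    """SWT and WP subband means/stds for the four wavelet bases.

    Subband naming follows the level-concatenated convention: ``A1`` is the
    level-1 approximation, ``A2A1`` the approximation of ``A1``, and for the
    wavelet packet ``Dv2Dv1`` the vertical detail of ``Dv1``.
    """
    data = _pad_dyadic(np.asarray(patch, float))
    feats: dict[str, float] = {}
    for base_name, wavelet in WAVELET_BASES.items():
        coeffs = pywt.swt2(data, wavelet, level=2, trim_approx=False)
        # pywt orders swt2 output from the deepest level to level 1
        (a2, (h2, v2, d2)), (a1, (h1, v1, d1)) = coeffs
        swt_bands = {"A1": a1, "Dh1": h1, "Dv1": v1, "Dd1": d1,
                     "A2A1": a2, "Dh2A1": h2, "Dv2A1": v2, "Dd2A1": d2}
        for band, arr in swt_bands.items():
            feats[f"SWT {band} ({base_name}) mean"] = float(np.mean(arr))
            feats[f"SWT {band} ({base_name}) std."] = float(np.std(arr))
        wp = pywt.WaveletPacket2D(data=data, wavelet=wavelet, mode="symmetric",
                                  maxlevel=2)
        for node in wp.get_level(1, order="natural"):
            band = f"{_SUBBAND_LETTER[node.path]}1"
            feats[f"WP {band} ({base_name}) mean"] = float(np.mean(node.data))
            feats[f"WP {band} ({base_name}) std."] = float(np.std(node.data))
        for node in wp.get_level(2, order="natural"):
            p1, p2 = node.path[0], node.path[1]
            band = f"{_SUBBAND_LETTER[p2]}2{_SUBBAND_LETTER[p1]}1"
            feats[f"WP {band} ({base_name}) mean"] = float(np.mean(node.data))
            feats[f"WP {band} ({base_name}) std."] = float(np.std(node.data))
    return feats


def _haralick(p: np.ndarray) -> dict:
    """The 12 Haralick statistics of one normalized co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(ng)[:, None]
    j = np.arange(ng)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def _ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)))

    asm = float(np.sum(p**2))
    k_diff = np.abs(i - j)
    p_diff = np.array([p[k_diff == k].sum() for k in range(ng)])
    k_sum = i + j
    p_sum = np.array([p[k_sum == k].sum() for k in range(2 * ng - 1)])
    contrast = float(np.sum(np.arange(ng) ** 2 * p_diff))
    mu_x = float(np.sum(np.arange(ng) * px))
    mu_y = float(np.sum(np.arange(ng) * py))
    var_x = float(np.sum((np.arange(ng) - mu_x) ** 2 * px))
    var_y = float(np.sum((np.arange(ng) - mu_y) ** 2 * py))
    if var_x > 0 and var_y > 0:
        corr = float((np.sum(i * j * p) - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        corr = 0.0
    variance = float(np.sum((i - mu_x) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (i - j) ** 2)))
    ks = np.arange(2 * ng - 1)
    sum_avg = float(np.sum(ks * p_sum))
    sum_var = float(np.sum((ks - sum_avg) ** 2 * p_sum))
    sum_ent = _ent(p_sum)
    entropy = _ent(p.ravel())
    kd = np.arange(ng)
    diff_avg = float(np.sum(kd * p_diff))
    diff_var = float(np.sum((kd - diff_avg) ** 2 * p_diff))
    diff_ent = _ent(p_diff)
    hx, hy = _ent(px), _ent(py)
    mask = (px[:, None] * py[None, :]) > 0
    hxy1 = float(-np.sum(p[mask] * np.log((px[:, None] * py[None, :])[mask])))
    imc = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    return dict(zip(HARALICK_NAMES, (
        asm, contrast, corr, variance, idm, sum_avg, sum_var, sum_ent,
        entropy, diff_var, diff_ent, float(imc),
    )))


def glcm_features(patch: np.ndarray) -> dict:
    """48 Haralick features: 12 statistics x 4 directions, 32-level GLCM.

    The patch is quantized to 32 grey levels over its own intensity range;
    co-occurrence matrices use offset distance 1 and are symmetric and
    normalized.  A constant patch yields the degenerate single-level matrix
    (ASM 1, contrast 0, entropy 0; correlation set to 0, logged).
    """
    patch = np.asarray(patch, float)
    lo, hi = patch.min(), patch.max()
    if hi > lo:
        q = np.minimum((patch - lo) / (hi - lo) * GLCM_LEVELS, GLCM_LEVELS - 1)
    else:
        log.info("constant ROI patch: degenerate co-occurrence matrix")
        q = np.zeros_like(patch)
    q = q.astype(np.uint8)
    angles = [np.deg2rad(a) for a in GLCM_ANGLES_DEG]
    glcm = graycomatrix(q, distances=[1], angles=angles, levels=GLCM_LEVELS,
                        symmetric=True, normed=True)
    feats = {}
    for ai, deg in enumerate(GLCM_ANGLES_DEG):
        stats = _haralick(glcm[:, :, 0, ai])
        for name, val in stats.items():
            feats[f"{deg}° {name}"] = val
    return feats


def polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return float(abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def extract_features(image: np.ndarray, tendon: Contour,
                     sheath_closed: np.ndarray | None = None) -> dict:
    """Full named feature vector for one hand image.

    Ordering of the returned dict is the documented canonical feature order
    (areas, then SWT/WP subbands per basis, then GLCM) and is used for tie
    breaking during feature selection.
    """
    feats: dict[str, float] = {}
    feats["Area inside Sheath"] = (
        polygon_area(np.asarray(sheath_closed, float))
        if sheath_closed is not None else polygon_area(tendon.points))
    feats["Area of tendon"] = polygon_area(tendon.points)
    roi = extract_roi(image, tendon)
    feats.update(wavelet_features(roi))
    feats.update(glcm_features(roi))
    return feats


# ---------------------------------------------------------------------------
# pair samples
# ---------------------------------------------------------------------------

@dataclass
class PairSample:
    """Per-subject left/right features and their difference vector."""

    left_features: dict
    right_features: dict
    label: str
    affected_side: str | None = None

    @property
    def difference(self) -> dict:
        """Affected minus contralateral for symptomatic pairs; right minus
        left for asymptomatic pairs."""
        if self.label == POSITIVE_LABEL and self.affected_side == "left":
            a, b = self.left_features, self.right_features
        else:
            a, b = self.right_features, self.left_features
        return {k: a[k] - b[k] for k in a}


def pair_feature_frame(samples) -> tuple[pd.DataFrame, np.ndarray]:
    """Difference-feature matrix and label array for a list of PairSamples."""
    rows = [s.difference for s in samples]
    X = pd.DataFrame(rows)
    y = np.array([s.label for s in samples])
    return X, y


# ---------------------------------------------------------------------------
# divergence-value feature selection
# ---------------------------------------------------------------------------

def divergence_value(sigma_normal: float, sigma_abnormal: float,
                     denominator: str = "product") -> float:
    """Class-spread divergence score of one feature.

    ``(sigma_n - sigma_a)^2 (1 + sigma_n + sigma_a)^2 / (sigma_n sigma_a)``;
    with ``denominator="doubled"`` the denominator is ``2 sigma_n sigma_a``.
    Zero when the class spreads are equal; grows with spread disparity.
    """
    if sigma_normal <= 0 or sigma_abnormal <= 0:
        raise ValueError("divergence value needs strictly positive class spreads")
    num = (sigma_normal - sigma_abnormal) ** 2 * (1 + sigma_normal + sigma_abnormal) ** 2
    den = sigma_normal * sigma_abnormal
    if denominator == "doubled":
        den = 2 * den
    elif denominator != "product":
        raise ValueError(f"unknown denominator mode '{denominator}'")
    return float(num / den)


def select_features(X: pd.DataFrame, y: np.ndarray, k: int = 20,
                    denominator: str = "product") -> list[str]:
    """Top-``k`` feature names by divergence value of the class spreads.

    Features with a zero spread in either class are skipped (logged); ties
    are broken by the documented feature order (stable sort).
    """
    pos = X[y == POSITIVE_LABEL]
    neg = X[y != POSITIVE_LABEL]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("feature selection needs >= 2 samples per class")
    scores = []
    skipped = 0
    for name in X.columns:
        sn = float(neg[name].std(ddof=0))
        sa = float(pos[name].std(ddof=0))
        if sn <= 0 or sa <= 0:
            skipped += 1
            continue
        scores.append((name, divergence_value(sn, sa, denominator)))
    if skipped:
        log.info("skipped %d features with zero class spread", skipped)
    scores.sort(key=lambda t: -t[1])  # stable: ties keep canonical order
    names = [n for n, _ in scores[:k]]
    if len(scores) < k:
        log.info("only %d valid features available (requested %d)", len(scores), k)
    return names


# ---------------------------------------------------------------------------
# SVM classifier
# ---------------------------------------------------------------------------

class TriggerFingerClassifier(BaseEstimator, ClassifierMixin):
    """Divergence-selected, standardized RBF-SVM pair classifier.

    Parameters
    ----------
    n_features : int
        Number of top-divergence features kept (default 20).
    C, gamma : SVM hyperparameters (RBF kernel).
    divergence_denominator : {"product", "doubled"}
        Reading of the divergence-value denominator.
    """

    def __init__(self, n_features: int = 20, C: float = 1.0, gamma="scale",
                 divergence_denominator: str = "product"):
        self.n_features = n_features
        self.C = C
        self.gamma = gamma
        self.divergence_denominator = divergence_denominator

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training needs both classes present")
        X = pd.DataFrame(X)
        self.selected_features_ = select_features(
            X, y, k=self.n_features, denominator=self.divergence_denominator)
        self.pipeline_ = make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=self.C, gamma=self.gamma))
        self.pipeline_.fit(X[self.selected_features_].to_numpy(), y)
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        return self.pipeline_.predict(X[self.selected_features_].to_numpy())


def train_classifier(samples, n_features: int = 20, **svm_kwargs):
    """Fit a :class:`TriggerFingerClassifier` on a list of PairSamples."""
    X, y = pair_feature_frame(samples)
    return TriggerFingerClassifier(n_features=n_features, **svm_kwargs).fit(X, y)


def evaluate_classifier(X: pd.DataFrame, y, n_repeats: int = 10,
                        classifier_kwargs: dict | None = None):
    """Repeated leave-one-pair-out evaluation.

    Feature selection and scaling are refit inside every fold.  Counts are
    aggregated over all repeats and folds (the repeat structure mirrors the
    totals of repeated full passes over the cohort).

    Returns
    -------
    cm : ConfusionMatrix (positive class = symptomatic)
    acc : float, percent
    prec : float, percent
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y)
    n = len(y)
    if n < 2 or len(np.unique(y)) < 2:
        raise ValueError("evaluation needs both classes present")
    kwargs = classifier_kwargs or {}
    tp = tn = fp = fn = 0
    for _rep in range(n_repeats):
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            clf = TriggerFingerClassifier(**kwargs).fit(X[mask], y[mask])
            pred = clf.predict(X[~mask])[0]
            truth = y[i]
            if truth == POSITIVE_LABEL:
                tp += pred == POSITIVE_LABEL
                fn += pred != POSITIVE_LABEL
            else:
                tn += pred != POSITIVE_LABEL
                fp += pred == POSITIVE_LABEL
    cm = ConfusionMatrix(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
    return cm, accuracy(cm), precision(cm) if cm.tp + cm.fp else float("nan")
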