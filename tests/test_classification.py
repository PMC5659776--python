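"""ROI extraction, wavelet/GLCM features, divergence selection and the SVM."""

import numpy as np
import pandas as pd
import pytest
import pywt

from atasm.classification import (
    PairSample,
    TriggerFingerClassifier,
    divergence_value,
    evaluate_classifier,
    extract_roi,
    glcm_features,
    pair_feature_frame,
    select_features,
    wavelet_features,
)
from atasm.contour import Contour
from conftest import circle_points


class TestRoi:
    def test_patch_indices_follow_centroid_arithmetic(self):
        yy, xx = np.mgrid[0:200, 0:200].astype(float)
        img = xx + 1000.0 * yy
        con = Contour(circle_points(n=20, r=15.0, center=(100.0, 80.0)))
        roi = extract_roi(img, con)
        assert roi.shape == (21, 41)
        assert roi[0, 0] == 80.0 + 1000.0 * 70.0
        assert roi[-1, -1] == 120.0 + 1000.0 * 90.0

    def test_constant_image_gives_constant_patch(self):
        img = np.full((100, 100), 42.0)
        con = Contour(circle_points(n=20, r=10.0, center=(50.0, 50.0)))
        assert np.all(extract_roi(img, con) == 42.0)

    def test_centroid_outside_image_rejected(self):
        con = Contour(circle_points(n=20, r=10.0, center=(500.0, 50.0)))
        with pytest.raises(ValueError, match="outside"):
            extract_roi(np.zeros((100, 100)), con)


class TestWaveletFeatures:
    def test_constant_patch_detail_bands_vanish(self):
        feats = wavelet_features(np.full((21, 41), 7.0))
        for name, val in feats.items():
            if "A" in name.split(" ")[1] and "D" not in name.split(" ")[1]:
                continue
            assert val == pytest.approx(0.0, abs=1e-9), name

    def test_swt_approximation_gain_matches_filter_oracle(self):
        c = 13.0
        feats = wavelet_features(np.full((21, 41), c))
        for base, wav in (("haar", "haar"), ("db4", "db4")):
            dc = np.sum(pywt.Wavelet(wav).dec_lo)
            assert feats[f"SWT A1 ({base}) mean"] == pytest.approx(c * dc**2, rel=1e-9)
            assert feats[f"SWT A2A1 ({base}) mean"] == pytest.approx(c * dc**4, rel=1e-9)

    def test_linearity_under_intensity_doubling(self):
        rng = np.random.default_rng(0)
        patch = rng.uniform(0, 255, (21, 41))
        f1 = wavelet_features(patch)
        f2 = wavelet_features(2.0 * patch)
        for name in f1:
            assert f2[name] == pytest.approx(2.0 * f1[name], rel=1e-9, abs=1e-9)

    def test_detail_bands_invariant_to_additive_shift(self):
        rng = np.random.default_rng(1)
        patch = rng.uniform(0, 200, (21, 41))
        f1 = wavelet_features(patch)
        f2 = wavelet_features(patch + 55.0)
        for name in f1:
            band = name.split(" ")[1]
            if band.startswith("D") and "A" not in band:
                assert f2[name] == pytest.approx(f1[name], abs=1e-8), name


class TestGlcmFeatures:
    def test_constant_patch_degenerate_matrix(self):
        feats = glcm_features(np.full((21, 41), 9.0))
        for deg in (0, 45, 90, 135):
            assert feats[f"{deg}° angular second moment"] == pytest.approx(1.0)
            assert feats[f"{deg}° contrast"] == 0.0
            assert feats[f"{deg}° entropy"] == 0.0
            assert feats[f"{deg}° correlation"] == 0.0

    def test_checkerboard_contrast_matches_hand_count(self):
        """On a two-level checkerboard every 0-degree neighbour pair differs
        by the full quantized range, so contrast = (levels-1)^2."""
        board = np.indices((8, 8)).sum(axis=0) % 2 * 100.0
        feats = glcm_features(board)
        assert feats["0° contrast"] == pytest.approx(31.0**2)
        assert feats["90° contrast"] == pytest.approx(31.0**2)
        # at 45 degrees diagonal neighbours are equal
        assert feats["45° contrast"] == pytest.approx(0.0)

    def test_feature_count_and_finiteness(self):
        rng = np.random.default_rng(2)
        feats = glcm_features(rng.uniform(0, 255, (21, 41)))
        assert len(feats) == 48
        assert all(np.isfinite(v) for v in feats.values())

    def test_contrast_invariant_to_additive_shift(self):
        rng = np.random.default_rng(3)
        patch = rng.uniform(0, 200, (21, 41))
        f1 = glcm_features(patch)
        f2 = glcm_features(patch + 40.0)
        for deg in (0, 45, 90, 135):
            assert f2[f"{deg}° contrast"] == pytest.approx(f1[f"{deg}° contrast"])


class TestDivergence:
    def test_reference_values(self):
        assert divergence_value(1.5, 1.5) == 0.0
        assert divergence_value(2.0, 1.0) == pytest.approx(8.0)
        assert divergence_value(2.0, 1.0, denominator="doubled") == pytest.approx(4.0)

    def test_class_swap_symmetry(self):
        assert divergence_value(0.7, 2.3) == pytest.approx(divergence_value(2.3, 0.7))

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            divergence_value(0.0, 1.0)


class TestFeatureSelection:
    def _frame(self, rng, n=20, planted="f00"):
        cols = {}
        for j in range(30):
            name = f"f{j:02d}"
            pos_sd = 6.0 if name == planted else 1.0
            pos = rng.normal(0, pos_sd, n // 2)
            neg = rng.normal(0, 1.0, n // 2)
            cols[name] = np.concatenate([pos, neg])
        y = np.array(["symptomatic"] * (n // 2) + ["asymptomatic"] * (n // 2))
        return pd.DataFrame(cols), y

    def test_planted_high_spread_feature_ranked_first(self):
        X, y = self._frame(np.random.default_rng(0))
        assert select_features(X, y, k=5)[0] == "f00"

    def test_k_larger_than_feature_count_returns_all(self):
        X, y = self._frame(np.random.default_rng(1))
        assert len(select_features(X, y, k=100)) == 30

    def test_ranking_matches_brute_force_sort_oracle(self):
        X, y = self._frame(np.random.default_rng(2))
        got = select_features(X, y, k=30)
        scores = {}
        for name in X.columns:
            sn = X[y == "asymptomatic"][name].std(ddof=0)
            sa = X[y == "symptomatic"][name].std(ddof=0)
            scores[name] = ((sn - sa) ** 2 * (1 + sn + sa) ** 2) / (sn * sa)
        oracle = sorted(X.columns, key=lambda n: -scores[n])
        assert got == oracle


class TestClassifier:
    def _separable_samples(self, rng, n=16):
        samples = []
        for i in range(n):
            label = "symptomatic" if i < n // 2 else "asymptomatic"
            offset = 5.0 if label == "symptomatic" else 0.0
            left = {f"f{j}": float(rng.normal(offset, 0.3)) for j in range(6)}
            right = {f"f{j}": float(rng.normal(0, 0.3)) for j in range(6)}
            samples.append(PairSample(left, right, label,
                                      "left" if label == "symptomatic" else None))
        return samples

    def test_separable_pairs_fit_perfectly(self):
        samples = self._separable_samples(np.random.default_rng(0))
        X, y = pair_feature_frame(samples)
        clf = TriggerFingerClassifier(n_features=4).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_single_class_training_rejected(self):
        samples = self._separable_samples(np.random.default_rng(1))
        X, _ = pair_feature_frame(samples)
        with pytest.raises(ValueError, match="both classes"):
            TriggerFingerClassifier().fit(X, ["symptomatic"] * len(X))

    def test_deterministic_given_fixed_data(self):
        samples = self._separable_samples(np.random.default_rng(2))
        X, y = pair_feature_frame(samples)
        p1 = TriggerFingerClassifier(n_features=4).fit(X, y).predict(X)
        p2 = TriggerFingerClassifier(n_features=4).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_label_permutation_control_shows_no_skill(self):
        """Permuted labels yield no classification skill.

        Leave-one-out accuracy under the null is biased *below* 50% (the
        held-out pair's class is the training minority), so the control is
        one-sided: permuted labels must never look better than chance plus
        the binomial band.
        """
        rng = np.random.default_rng(3)
        samples = []
        for i in range(24):
            label = "symptomatic" if i < 12 else "asymptomatic"
            left = {f"f{j}": float(rng.normal(0, 1.0)) for j in range(6)}
            right = {f"f{j}": float(rng.normal(0, 1.0)) for j in range(6)}
            samples.append(PairSample(left, right, label,
                                      "left" if label == "symptomatic" else None))
        X, y = pair_feature_frame(samples)
        accs = []
        for seed in range(5):
            y_perm = np.random.default_rng(seed).permutation(y)
            _, acc, _ = evaluate_classifier(X, y_perm, n_repeats=1)
            accs.append(acc)
        # 95% binomial band for 24 decisions is about +-20 points around 50
        assert max(accs) <= 75.0
        assert np.mean(accs) <= 60.0

    def test_confusion_counts_sum_to_repeats_times_pairs(self):
        samples = self._separable_samples(np.random.default_rng(4))
        X, y = pair_feature_frame(samples)
        cm, _, _ = evaluate_classifier(X, y, n_repeats=3)
        assert cm.total == 3 * len(X)

    def test_difference_orientation(self):
        left = {"f": 10.0}
        right = {"f": 4.0}
        sym_left = PairSample(left, right, "symptomatic", "left")
        assert sym_left.difference["f"] == 6.0
        sym_right = PairSample(left, right, "symptomatic", "right")
        assert sym_right.difference["f"] == -6.0
        normal = PairSample(left, right, "asymptomatic")
        assert normal.difference["f"] == -6.0
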