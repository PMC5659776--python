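"""Procrustes alignment, PCA shape model, synthesis and clamping."""

import numpy as np
import pytest

from atasm.contour import Contour, ContourError
from atasm.shape_model import (
    PointDistributionModel,
    ShapeParams,
    apply_pose,
    clamp_params,
    fit_pca,
    pose_from_alignment,
    procrustes_align,
    synthesize_shape,
)
from conftest import circle_points


def _ellipse(a, b, center=(0.0, 0.0), n=20, phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)], axis=1)


class TestProcrustes:
    def test_identical_shapes_align_to_normalized_mean(self):
        pts = _ellipse(40, 25, center=(100, 80))
        aligned, mean = procrustes_align([Contour(pts), Contour(pts.copy())])
        assert np.allclose(aligned[0].points, aligned[1].points, atol=1e-12)
        assert np.allclose(mean.points.mean(axis=0), 0.0, atol=1e-9)
        rms = np.sqrt(np.mean(np.sum(mean.points**2, axis=1)))
        assert rms == pytest.approx(1.0, abs=1e-9)

    def test_similarity_copy_recovered_exactly(self):
        pts = _ellipse(40, 25)
        moved = apply_pose(pts, (17.0, -4.0, 1.6, 0.7))
        aligned, _ = procrustes_align([Contour(pts), Contour(moved)])
        assert np.linalg.norm(aligned[0].points - aligned[1].points) < 1e-8

    def test_noisy_ellipses_match_svd_oracle(self):
        """Residual to the mean equals a closed-form one-shot SVD alignment."""
        rng = np.random.default_rng(0)
        shapes = [Contour(_ellipse(40, 25) + rng.normal(0, 1.0, (20, 2)))
                  for _ in range(5)]
        aligned, mean = procrustes_align(shapes)

        def svd_align(src, dst):
            # independent closed-form similarity Procrustes
            sc = src - src.mean(axis=0)
            dc = dst - dst.mean(axis=0)
            u, s, vt = np.linalg.svd(sc.T @ dc)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, d]) @ u.T
            scale = (s[0] + d * s[1]) / np.sum(sc**2)
            return scale * sc @ rot.T + dst.mean(axis=0)

        for raw, al in zip(shapes, aligned):
            oracle = svd_align(raw.points, mean.points)
            res_pkg = np.linalg.norm(al.points - mean.points)
            res_orc = np.linalg.norm(oracle - mean.points)
            assert res_pkg == pytest.approx(res_orc, abs=1e-6)

    def test_invariant_to_similarity_pretransform_of_input_set(self):
        rng = np.random.default_rng(1)
        shapes = [_ellipse(40, 25) + rng.normal(0, 0.5, (20, 2)) for _ in range(6)]
        _, mean_a = procrustes_align([Contour(s) for s in shapes])
        moved = [apply_pose(s, (250.0, -31.0, 2.3, 1.1)) for s in shapes]
        _, mean_b = procrustes_align([Contour(s) for s in moved])
        rms = np.sqrt(np.mean((mean_a.points - mean_b.points) ** 2))
        assert rms < 1e-6

    def test_coincident_points_rejected(self):
        flat = Contour(np.zeros((20, 2)))
        with pytest.raises(ContourError):
            procrustes_align([flat, flat])


class TestPCA:
    def test_identical_shapes_give_zero_modes(self):
        pts = _ellipse(40, 25)
        model = fit_pca([Contour(pts) for _ in range(5)])
        assert model.n_modes_ == 0
        assert np.allclose(model.all_eigenvalues_, 0.0, atol=1e-12)

    def test_rank_one_variation_gives_single_mode(self):
        # radial cos(2t) field on a circle: orthogonal to the similarity
        # modes, so alignment keeps the one-mode family one-dimensional
        t = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        base = circle_points(n=20, r=1.0)
        direction = base * np.cos(2 * t)[:, None]
        shapes = [Contour(base + a * direction) for a in (-0.06, -0.02, 0.02, 0.06)]
        model = fit_pca(shapes)
        ev = model.all_eigenvalues_
        assert ev[0] > 1e-6
        # unit-RMS scale normalization leaves a second-order residue, so the
        # trailing eigenvalues are only near-zero relative to the first
        assert np.all(ev[1:] < 1e-3 * ev[0] + 1e-12)

    def test_two_mode_generator_variances_recovered(self):
        """Planted 2-mode shape variation is recovered by the eigenvalues."""
        t = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        base = circle_points(n=20, r=1.0)
        # radial deformation fields orthogonal to similarity modes
        d1 = base * np.cos(2 * t)[:, None]
        d2 = base * np.cos(3 * t)[:, None]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        s1, s2 = 0.06, 0.03
        rng = np.random.default_rng(7)
        shapes = [Contour(base + s1 * rng.standard_normal() * d1
                          + s2 * rng.standard_normal() * d2)
                  for _ in range(60)]
        model = fit_pca(shapes)
        ev = model.all_eigenvalues_
        # the base circle already has unit RMS radius, so alignment leaves the
        # planted variances on their original scale
        assert ev[0] == pytest.approx(s1**2, rel=0.4)
        assert ev[1] == pytest.approx(s2**2, rel=0.4)
        assert ev[2] < 0.05 * ev[1]

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(2)
        shapes = [Contour(_ellipse(40, 25) + rng.normal(0, 1, (20, 2)))
                  for _ in range(8)]
        model = fit_pca(shapes)
        vecs = np.stack([c.as_vector() for c in model.aligned_])
        total = np.trace(np.cov(vecs.T, bias=True))
        assert model.all_eigenvalues_.sum() == pytest.approx(total, rel=1e-9)

    def test_fewer_than_two_shapes_rejected(self):
        with pytest.raises(ContourError):
            fit_pca([Contour(_ellipse(40, 25))])


class TestSynthesisAndClamp:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(3)
        shapes = [Contour(_ellipse(40, 25) + rng.normal(0, 1, (20, 2)))
                  for _ in range(10)]
        return fit_pca(shapes)

    def test_zero_b_identity_pose_gives_mean_shape(self, model):
        out = synthesize_shape(model, ShapeParams(np.zeros(model.n_modes_)))
        assert np.allclose(out.as_vector(), model.mean_shape_, atol=1e-12)

    def test_pose_translation_shifts_mean_shape(self, model):
        out = synthesize_shape(
            model, ShapeParams(np.zeros(model.n_modes_), (10.0, 5.0, 1.0, 0.0)))
        expected = model.mean_shape_.reshape(-1, 2) + np.array([10.0, 5.0])
        assert np.allclose(out.points, expected, atol=1e-12)

    def test_first_mode_synthesis_matches_vector_arithmetic(self, model):
        b = np.zeros(model.n_modes_)
        b[0] = 3 * np.sqrt(model.eigenvalues_[0])
        out = synthesize_shape(model, ShapeParams(b))
        oracle = model.mean_shape_ + b[0] * model.components_[:, 0]
        assert np.allclose(out.as_vector(), oracle, atol=1e-10)

    def test_clamp_behaviour(self, model):
        lam = model.eigenvalues_
        inside = ShapeParams(0.5 * np.sqrt(lam))
        assert np.allclose(clamp_params(inside, model).b, inside.b)
        outside = ShapeParams(10.0 * np.sqrt(lam))
        assert np.allclose(clamp_params(outside, model).b, 3.0 * np.sqrt(lam))

    def test_zero_eigenvalue_mode_clamped_to_zero(self):
        pts = _ellipse(40, 25)
        direction = np.zeros((20, 2))
        direction[:, 1] = np.sin(2 * np.linspace(0, 2 * np.pi, 20, endpoint=False))
        shapes = [Contour(pts + a * direction) for a in (-0.5, 0.0, 0.5)]
        model = PointDistributionModel(variance_retained=1.0).fit(shapes)
        zero_modes = model.eigenvalues_ < 1e-12
        params = model.clamp_params(ShapeParams(np.ones(model.n_modes_)))
        assert np.all(params.b[zero_modes] == 0.0)

    def test_project_synthesize_round_trip(self, model):
        target = model.aligned_[3]
        params = model.project(target)
        recon = model.synthesize(params)
        discarded = model.all_eigenvalues_[model.n_modes_:].sum()
        err = np.mean(np.sum((recon.points - target.points) ** 2, axis=1))
        assert err <= 40 * discarded / 20 + 1e-8

    def test_columns_orthonormal_and_eigenvalues_sorted(self, model):
        p = model.components_
        assert np.allclose(p.T @ p, np.eye(model.n_modes_), atol=1e-10)
        assert np.all(np.diff(model.eigenvalues_) <= 1e-12)

    def test_pose_from_alignment_recovers_known_pose(self):
        pts = _ellipse(40, 25)
        pose = (12.0, -3.0, 1.4, 0.5)
        est = pose_from_alignment(pts, apply_pose(pts, pose))
        assert np.allclose(est, pose, atol=1e-9)
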