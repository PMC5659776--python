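"""Energy terms, adaptive weight training and the weighted objective."""

import numpy as np
import pytest

from atasm.contour import Contour, resample_contour
from atasm.energy import (
    EnergyEvaluator,
    EnergyVector,
    EnergyWeights,
    SEARCH_LINE,
    TERM_NAMES,
    area_gradient_term,
    curvature_term,
    line_gradient_term,
    total_energy,
    train_weights,
    weights_from_line_table,
)
from atasm.texture import TextureProfileModel, energy_texture_images, sample_profile
from atasm.contour import outward_normals
from conftest import circle_points


def _diamond_contour(cx=40.0, cy=45.0, r=15.0):
    """Diamond (45-deg square): distinct extremal anchors, vertical normal at
    the top vertex."""
    corners = np.array([[cx, cy - r], [cx + r, cy], [cx, cy + r], [cx - r, cy]])
    raw = np.vstack([np.linspace(corners[i], corners[(i + 1) % 4], 10, endpoint=False)
                     for i in range(4)])
    return resample_contour(raw)


class TestCurvature:
    def test_reference_angles(self):
        # three collinear points -> pi; right angle -> pi/2; 60 deg wedge -> pi/3
        collinear = Contour(np.array([[0.0, 0], [1, 0], [2, 0], [2, 2], [0, 2]]))
        assert curvature_term(collinear, 1) == pytest.approx(np.pi)
        right = Contour(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        assert curvature_term(right, 1) == pytest.approx(np.pi / 2)
        wedge = Contour(np.array([[np.cos(np.pi / 3), np.sin(np.pi / 3)],
                                  [0.0, 0.0], [1.0, 0.0], [0.0, 2.0]]))
        assert curvature_term(wedge, 1) == pytest.approx(np.pi / 3)

    def test_coincident_neighbours_return_pi(self):
        degenerate = Contour(np.array([[0.0, 0], [0, 0], [1, 1], [0, 2]]))
        assert curvature_term(degenerate, 1) == pytest.approx(np.pi)


class TestGradientTerms:
    @pytest.fixture()
    def step_image(self):
        # bright below row 30 ("inside"), dark above
        img = np.full((100, 100), 50.0)
        img[30:, :] = 200.0
        return img

    def test_step_gradients(self, step_image):
        con = _diamond_contour()
        top = int(np.argmin(con.points[:, 1]))  # on y=30, normal (0,-1)
        assert area_gradient_term(step_image, con, top, "tendon") == pytest.approx(150.0)
        assert line_gradient_term(step_image, con, top, "tendon") == pytest.approx(150.0)
        # sheath flips the sign
        assert area_gradient_term(step_image, con, top, "sheath") == pytest.approx(-150.0)
        assert line_gradient_term(step_image, con, top, "sheath") == pytest.approx(-150.0)

    def test_uniform_image_gives_zero(self):
        img = np.full((100, 100), 90.0)
        con = _diamond_contour()
        for i in range(con.n_points):
            assert area_gradient_term(img, con, i) == pytest.approx(0.0, abs=1e-9)
            assert line_gradient_term(img, con, i) == pytest.approx(0.0, abs=1e-9)

    def test_line_term_sees_narrow_band_stronger_than_area_term(self):
        """A dark band at a small standoff outside a bright disk: the 5-px
        line mask reaches it while the 3x3 window (centred 2 px out) mostly
        misses it (direct-sampling check)."""
        img = np.full((120, 120), 160.0)
        yy, xx = np.mgrid[0:120, 0:120].astype(float)
        r = np.hypot(xx - 60, yy - 60)
        img[(r >= 32.5) & (r < 36.5)] = 40.0
        con = resample_contour(circle_points(n=720, r=30.0, center=(60.0, 60.0)))
        i = int(np.argmin(con.points[:, 1]))
        line = line_gradient_term(img, con, i, "tendon")
        area = area_gradient_term(img, con, i, "tendon")
        assert line > area > 0

    def test_sheath_terms_are_negated_tendon_terms(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (100, 100))
        con = _diamond_contour()
        for i in range(0, 20, 5):
            assert area_gradient_term(img, con, i, "sheath") == pytest.approx(
                -area_gradient_term(img, con, i, "tendon"))
            assert line_gradient_term(img, con, i, "sheath") == pytest.approx(
                -line_gradient_term(img, con, i, "tendon"))


class TestTextureEnergies:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (100, 100))
        con = resample_contour(circle_points(n=720, r=25.0, center=(50.0, 50.0)))
        profiles = {name: sample_profile(tex, con).values
                    for name, tex in energy_texture_images(img).items()}
        return img, con, profiles

    def test_profile_match_gives_zero_maximum(self, setup):
        img, con, profiles = setup
        model = TextureProfileModel(mean_profiles=profiles, n_training=1)
        ev = EnergyEvaluator(img, model, "tendon")
        terms = ev.terms(con).values
        assert terms[TERM_NAMES.index("gabor")].sum() == pytest.approx(0.0, abs=1e-9)
        assert terms[TERM_NAMES.index("laws")].sum() == pytest.approx(0.0, abs=1e-9)

    def test_unit_offset_profile_gives_minus_100(self, setup):
        img, con, profiles = setup
        shifted = {k: v + 1.0 for k, v in profiles.items()}
        model = TextureProfileModel(mean_profiles=shifted, n_training=1)
        ev = EnergyEvaluator(img, model, "tendon")
        terms = ev.terms(con).values
        assert terms[TERM_NAMES.index("gabor")].sum() == pytest.approx(-100.0)
        assert terms[TERM_NAMES.index("laws")].sum() == pytest.approx(-100.0)

    def test_random_profiles_match_brute_force_ssd(self, setup):
        img, con, profiles = setup
        rng = np.random.default_rng(4)
        model_profiles = {k: rng.uniform(-10, 10, 100) for k in profiles}
        model = TextureProfileModel(mean_profiles=model_profiles, n_training=1)
        ev = EnergyEvaluator(img, model, "tendon")
        terms = ev.terms(con).values
        for key in ("gabor", "laws"):
            feat = "gabor_imag_0deg" if key == "gabor" else "laws_E5L5"
            oracle = -float(np.sum((model_profiles[feat] - profiles[feat]) ** 2))
            assert terms[TERM_NAMES.index(key)].sum() == pytest.approx(oracle, rel=1e-9)


class TestTotalEnergy:
    def test_weighted_sum_reference_cases(self):
        con = Contour(circle_points(n=20, r=10.0, center=(50, 50)))
        rng = np.random.default_rng(5)
        f = rng.normal(size=(5, 20))
        energy = EnergyVector(f, con)
        ones = EnergyWeights(np.ones((5, 20)))
        zeros = EnergyWeights(np.zeros((5, 20)))
        assert total_energy(energy, ones) == pytest.approx(f.sum())
        assert total_energy(energy, zeros) == 0.0
        w = EnergyWeights(rng.uniform(0, 2, (5, 20)))
        brute = sum(w.weights[k, i] * f[k, i] for k in range(5) for i in range(20))
        assert total_energy(energy, w) == pytest.approx(brute)

    def test_shape_mismatch_rejected(self):
        con = Contour(circle_points(n=20, r=10.0, center=(50, 50)))
        energy = EnergyVector(np.zeros((5, 20)), con)
        with pytest.raises(ValueError, match="mismatch"):
            total_energy(energy, EnergyWeights(np.ones((5, 19))))


class TestWeightTraining:
    def test_line_table_reference_cases(self):
        # constant line -> sigma 0 -> weight 0
        assert weights_from_line_table(np.full((1, 21), 3.0), 10)[0] == 0.0
        # truth at the line max with spread s -> weight = s
        line = np.concatenate([np.linspace(0, 0.9, 10), [1.0], np.linspace(0.9, 0, 10)])
        w = weights_from_line_table(line[None, :], 10)[0]
        assert w == pytest.approx(line.std())
        # zero maximum -> contribution zero
        assert weights_from_line_table(-np.abs(line)[None, :] - 1.0, 10)[0] >= 0.0
        assert weights_from_line_table(np.zeros((1, 21)), 10)[0] == 0.0

    def test_hand_built_tables_match_spreadsheet_mean(self):
        """Two images with hand-built line responses reproduce mean(sigma*F/Fmax)."""
        t1 = np.array([1.0, 2.0, 4.0, 2.0, 1.0])
        t2 = np.array([0.0, 3.0, 3.0, 6.0, 0.0])
        w1 = t1.std() * t1[2] / t1.max()
        w2 = t2.std() * t2[2] / t2.max()
        got = np.mean([weights_from_line_table(t1[None], 2)[0],
                       weights_from_line_table(t2[None], 2)[0]])
        assert got == pytest.approx((w1 + w2) / 2)

    def test_train_weights_matches_scalar_loop_oracle(self, training_set):
        """Vectorized weight training equals a per-point scalar re-evaluation."""
        image, truth, _ = training_set[0]
        con = truth["tendon"]
        model_profiles = {
            name: sample_profile(tex, con).values
            for name, tex in energy_texture_images(image).items()}
        pm = TextureProfileModel(mean_profiles=model_profiles, n_training=1)
        weights = train_weights([image], [con], pm, target="tendon")
        assert weights.weights.shape == (5, 20)
        assert np.all(weights.weights >= 0)

        ev = EnergyEvaluator(image, pm, "tendon")
        normals = outward_normals(con)
        for i in (0, 7, 13):
            table = np.zeros((5, len(SEARCH_LINE)))
            for d_idx, d in enumerate(SEARCH_LINE):
                pts = con.points.copy()
                pts[i] = con.points[i] + d * normals[i]
                table[:, d_idx] = ev.batch_terms(pts)[:, i]
            oracle = weights_from_line_table(table, int(np.flatnonzero(SEARCH_LINE == 0)[0]))
            assert np.allclose(weights.weights[:, i], oracle, rtol=1e-8, atol=1e-10)


class TestObjectiveDiscriminativeness:
    def test_truth_energy_beats_random_perturbations(self, tendon_segmenter,
                                                     speckled_phantom):
        """The trained objective peaks at the true contour (>= 95/100 trials)."""
        image, truth, _ = speckled_phantom
        ev = EnergyEvaluator(image, tendon_segmenter.texture_model_, "tendon")
        w = tendon_segmenter.weights_
        e_truth = ev.batch_total(truth["tendon"].points[None], w)[0]
        rng = np.random.default_rng(0)
        perturbed = truth["tendon"].points[None] + rng.normal(0, 3.0, (100, 20, 2))
        e_pert = ev.batch_total(perturbed, w)
        assert np.mean(e_pert < e_truth) >= 0.95
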