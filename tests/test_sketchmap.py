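"""Sketch-map tests: sigmoid closed forms, landmark selection, stress
minimization and out-of-sample placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from conjmap.sketchmap import (LandmarkSet, SigmoidParams, SketchMapModel,
                               classical_mds, fit_sketchmap, invert_sigmoid,
                               landmark_stress, project, select_landmarks,
                               sigmoid_transform)


DEFAULT_PARAMS = SigmoidParams()  # sigma=5.9, A=12, B=4, a=2, b=4


class TestSigmoid:
    def test_zero_maps_to_zero(self):
        assert sigmoid_transform(0.0, 5.9, 12, 4) == 0.0

    @pytest.mark.parametrize("a,b", [(12, 4), (2, 4), (1, 1), (7, 3)])
    def test_half_at_switching_distance(self, a, b):
        assert sigmoid_transform(5.9, 5.9, a, b) == pytest.approx(0.5,
                                                                  abs=1e-14)

    def test_matches_arbitrary_precision_evaluation(self):
        """F(2*sigma) for a=2, b=4 against sympy at 50 digits."""
        import sympy
        sigma, a, b = sympy.Rational(59, 10), 2, 4
        r = 2 * sigma
        expected = 1 - (1 + (sympy.Integer(2) ** sympy.Rational(a, b) - 1)
                        * (r / sigma) ** a) ** sympy.Rational(-b, a)
        got = sigmoid_transform(2 * 5.9, 5.9, 2, 4)
        assert got == pytest.approx(float(expected.evalf(50)), abs=1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 50), st.floats(0.01, 50))
    def test_monotone_and_bounded(self, r1, r2):
        lo, hi = sorted([r1, r2])
        f_lo = sigmoid_transform(lo, 5.9, 12, 4)
        f_hi = sigmoid_transform(hi, 5.9, 12, 4)
        assert 0 <= f_lo <= f_hi < 1

    def test_limit_is_one(self):
        assert sigmoid_transform(1e6, 5.9, 2, 4) == pytest.approx(1.0,
                                                                  abs=1e-6)

    def test_hd_steeper_than_ld_at_sigma(self):
        """The high-dimensional transform switches more sharply at sigma."""
        eps = 1e-6
        slope_hd = (DEFAULT_PARAMS.hd(5.9 + eps) - DEFAULT_PARAMS.hd(5.9 - eps))
        slope_ld = (DEFAULT_PARAMS.ld(5.9 + eps) - DEFAULT_PARAMS.ld(5.9 - eps))
        assert slope_hd > slope_ld

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_transform(-0.1, 5.9, 2, 4)

    def test_inverse_round_trip(self):
        for f in (0.0, 0.1, 0.5, 0.9):
            r = invert_sigmoid(f, 5.9, 2, 4)
            assert sigmoid_transform(r, 5.9, 2, 4) == pytest.approx(f,
                                                                    abs=1e-12)


class TestLandmarks:
    def test_all_points_selected_gives_unit_weights(self, rng):
        v = rng.normal(size=(12, 4))
        lm = select_landmarks(v, 12, gamma=0.5, seed=0)
        assert sorted(lm.indices) == list(range(12))
        np.testing.assert_array_equal(lm.weights, np.ones(12))

    def test_pure_minmax_includes_most_distant_pair(self, rng):
        """gamma=0: greedy farthest-point, seeded from the diameter pair."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            v = r.normal(size=(40, 3))
            d = pdist(v)
            from scipy.spatial.distance import squareform
            i, j = np.unravel_index(np.argmax(squareform(d)), (40, 40))
            lm = select_landmarks(v, 5, gamma=0.0, seed=seed)
            assert {i, j} <= set(lm.indices)

    def test_same_seed_is_deterministic(self, rng):
        v = rng.normal(size=(100, 6))
        a = select_landmarks(v, 20, gamma=0.1, seed=7)
        b = select_landmarks(v, 20, gamma=0.1, seed=7)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_weights_count_nearest_points(self, rng):
        v = rng.normal(size=(50, 3))
        lm = select_landmarks(v, 10, gamma=0.2, seed=1)
        assert lm.weights.sum() == 50

    def test_too_many_landmarks_rejected(self, rng):
        with pytest.raises(ValueError):
            select_landmarks(rng.normal(size=(5, 2)), 6)


def equilateral_expected_side(params, d):
    """Root-finding oracle: the side r* with F_ld(r*) = F_hd(d)."""
    target = float(params.hd(d))
    return brentq(lambda r: float(params.ld(r)) - target, 1e-9, 1e4,
                  xtol=1e-12)


class TestFit:
    def test_three_equidistant_points_form_equilateral_triangle(self):
        """Final side length solves F_ld(r*) = F_hd(d) (1D root oracle)."""
        d = 4.0
        # three points pairwise at distance d in 3D
        v = np.array([[0, 0, 0], [d, 0, 0],
                      [d / 2, d * np.sqrt(3) / 2, 0.0]])
        lm = LandmarkSet(indices=[0, 1, 2], vectors=v, weights=[1, 1, 1])
        model = fit_sketchmap(lm, DEFAULT_PARAMS, seed=0, tol=1e-15)
        sides = pdist(model.coordinates)
        r_star = equilateral_expected_side(DEFAULT_PARAMS, d)
        np.testing.assert_allclose(sides, r_star, rtol=1e-4)

    def test_two_landmarks_rejected(self):
        lm = LandmarkSet(indices=[0, 1], vectors=np.eye(2), weights=[1, 1])
        with pytest.raises(ValueError):
            fit_sketchmap(lm)

    def test_stress_not_above_mds_initialization(self, rng):
        v = rng.normal(size=(20, 5)) * 3
        lm = select_landmarks(v, 20, gamma=1.0, seed=0)
        params = SigmoidParams(sigma=2.0)
        model = fit_sketchmap(lm, params, seed=0)
        fhd = params.hd(pdist(v))
        from scipy.spatial.distance import squareform
        x0 = classical_mds(squareform(fhd))
        spread = np.max(pdist(x0))
        x0 = x0 * (params.sigma / spread) * 2.0
        init_stress = landmark_stress(x0, lm, params)
        assert model.stress <= init_stress + 1e-12

    def test_stress_invariant_under_rigid_map_motions(self, rng):
        v = rng.normal(size=(10, 4))
        lm = select_landmarks(v, 10, gamma=1.0, seed=0)
        params = SigmoidParams(sigma=1.0)
        coords = rng.normal(size=(10, 2))
        s0 = landmark_stress(coords, lm, params)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        for moved in (coords @ rot.T,            # rotation
                      coords + [3.0, -1.0],      # translation
                      coords * [-1.0, 1.0]):     # reflection
            assert landmark_stress(moved, lm, params) == pytest.approx(
                s0, rel=1e-12)

    def test_same_seed_reproduces_model_exactly(self, rng):
        v = rng.normal(size=(30, 6)) * 2
        lm = select_landmarks(v, 15, gamma=0.1, seed=3)
        params = SigmoidParams(sigma=2.5)
        a = fit_sketchmap(lm, params, seed=5)
        b = fit_sketchmap(lm, params, seed=5)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress


class TestProject:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(42)
        centers = rng.normal(scale=6.0, size=(4, 8))
        v = np.vstack([c + rng.normal(scale=0.3, size=(25, 8))
                       for c in centers])
        lm = select_landmarks(v, 30, gamma=0.1, seed=0)
        return v, fit_sketchmap(lm, SigmoidParams(sigma=4.0), seed=0)

    def test_landmark_self_consistency(self, fitted):
        """Projecting a landmark's own vector lands on its fitted position."""
        _, model = fitted
        placed = project(model.landmarks.vectors, model)
        err = np.linalg.norm(placed - model.coordinates, axis=1)
        assert np.median(err) < 0.1

    def test_duplicated_rows_project_identically(self, fitted):
        v, model = fitted
        rows = np.vstack([v[3], v[3], v[7], v[3]])
        p = project(rows, model)
        np.testing.assert_array_equal(p[0], p[1])
        np.testing.assert_array_equal(p[0], p[3])

    def test_symmetric_point_projects_to_square_center(self):
        """Equidistant from the landmarks of a symmetric square -> center."""
        square = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]],
                          dtype=float) * 3
        lm = LandmarkSet(indices=np.arange(4), vectors=square,
                         weights=np.ones(4))
        model = fit_sketchmap(lm, SigmoidParams(sigma=3.0), seed=0)
        apex = np.array([[0.0, 0.0, 10.0]])  # equidistant from all corners
        p = project(apex, model)[0]
        center = model.coordinates.mean(axis=0)
        assert np.linalg.norm(p - center) < 0.15

    def test_dimension_mismatch_rejected(self, fitted):
        _, model = fitted
        with pytest.raises(ValueError):
            project(np.zeros((2, 5)), model)


def test_model_json_round_trip(tmp_path, rng):
    v = rng.normal(size=(12, 4))
    lm = select_landmarks(v, 8, gamma=0.25, seed=2)
    model = fit_sketchmap(lm, SigmoidParams(sigma=1.5), seed=2)
    path = model.to_json(tmp_path / "model.json")
    back = SketchMapModel.from_json(path)
    np.testing.assert_allclose(back.coordinates, model.coordinates)
    assert back.stress == pytest.approx(model.stress)
    assert back.params == model.params
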