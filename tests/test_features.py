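"""Descriptive metrics, parameter-space PCA, skill axes, score surfaces."""

import numpy as np
import pytest

from incise import (
    ForceProfile,
    PARAMETER_NAMES,
    descriptive_metrics,
    fit_feature_space,
    parameter_vector,
    score_surface,
    skill_axes,
)
from tests.test_regime import make_model


def profile_4s(samples):
    """A profile spanning exactly 4 s (121 samples at 30 Hz)."""
    return ForceProfile(samples=samples, rate=30.0)


class TestDescriptiveMetrics:
    def test_constant_profile_closed_forms(self):
        m = descriptive_metrics(profile_4s(np.full(121, 0.4)))
        assert m.mean_force == pytest.approx(0.4)
        assert m.force_std == 0.0
        assert m.peak_force == pytest.approx(0.4)
        assert m.scaled_force == pytest.approx(1.0)
        assert m.force_derivative == 0.0
        assert m.force_integral == pytest.approx(1.6)

    def test_linear_ramp_closed_forms(self):
        m = descriptive_metrics(profile_4s(np.linspace(0, 1, 121)))
        assert m.mean_force == pytest.approx(0.5)
        assert m.peak_force == pytest.approx(1.0)
        assert m.scaled_force == pytest.approx(0.5)
        assert m.force_derivative == pytest.approx(0.25)
        assert m.force_integral == pytest.approx(2.0)

    def test_random_profile_matches_bruteforce(self, random_profile):
        m = descriptive_metrics(random_profile)
        s, dt = random_profile.samples, random_profile.dt
        assert m.mean_force == pytest.approx(sum(s) / len(s))
        assert m.peak_force == max(s)
        assert m.force_derivative == pytest.approx(
            sum(abs(s[i + 1] - s[i]) for i in range(len(s) - 1)) / (len(s) - 1) / dt
        )
        assert m.force_integral == pytest.approx(
            sum((s[i] + s[i + 1]) / 2 * dt for i in range(len(s) - 1))
        )
        assert m.peak_force >= m.mean_force
        assert 0 < m.scaled_force <= 1

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="caled force"):
            descriptive_metrics(profile_4s(np.zeros(121)))

    def test_rescaling_behaviour(self, random_profile):
        base = descriptive_metrics(random_profile)
        doubled = descriptive_metrics(
            ForceProfile(samples=2 * random_profile.samples, rate=30.0)
        )
        assert doubled.mean_force == pytest.approx(2 * base.mean_force)
        assert doubled.scaled_force == pytest.approx(base.scaled_force)  # invariant
        assert doubled.force_integral == pytest.approx(2 * base.force_integral)
        assert doubled.force_derivative == pytest.approx(2 * base.force_derivative)


class TestParameterVector:
    def test_fixed_layout(self):
        m = make_model(v=(1, 6), sigma2=(0.1225, 0.1225), q12=0.05, q21=0.05)
        np.testing.assert_allclose(
            parameter_vector(m), [1, 6, 0.1225, 0.1225, 0.05, 0.05]
        )
        assert PARAMETER_NAMES == ("v_L", "v_U", "sigma2_L", "sigma2_U", "q12", "q21")

    def test_models_differing_only_in_q21(self):
        a = parameter_vector(make_model(q12=0.1, q21=0.05))
        b = parameter_vector(make_model(q12=0.1, q21=0.25))
        diff = np.nonzero(a != b)[0]
        np.testing.assert_array_equal(diff, [5])

    def test_serialization_round_trip_preserves_vector(self):
        from incise import RegimeModel

        m = make_model(v=(1.3, 5.7), sigma2=(0.04, 0.09), q12=0.12, q21=0.03)
        back = RegimeModel.from_json(m.to_json())
        np.testing.assert_array_equal(parameter_vector(m), parameter_vector(back))

    def test_non_two_regime_model_rejected(self):
        from incise import RegimeModel

        m3 = RegimeModel(
            v=[1, 2, 3],
            sigma2=[0.1] * 3,
            Q=np.full((3, 3), 1 / 3),
            pi0=[1 / 3] * 3,
        )
        with pytest.raises(ValueError):
            parameter_vector(m3)


def two_cluster_vectors(n_per=10, seed=0):
    """Two behaviour clusters separated only along (v_L down, q21 up);
    the other coordinates are uninformative noise."""
    g = np.random.default_rng(seed)
    base = np.array([2.0, 5.0, 0.1, 0.1, 0.08, 0.08])
    X = np.tile(base, (2 * n_per, 1))
    labels = np.repeat([0, 1], n_per)
    X[labels == 1, 0] -= 1.0  # v_L drops
    X[labels == 1, 5] += 0.15  # q21 rises
    noise_sd = np.array([0.02, 0.3, 0.02, 0.02, 0.02, 0.003])
    X += g.normal(0, 1, X.shape) * noise_sd
    return X, labels


class TestFeatureSpace:
    def test_line_in_parameter_space_is_one_component(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, 2.0, 0.5, 0.1, 0.3, 0.2]) + 1.0
        space = fit_feature_space(X)
        assert space.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal_and_variance_ordered(self, rng):
        X = rng.normal(size=(40, 6)) * [1, 2, 0.5, 0.2, 0.05, 0.04] + 1
        space = fit_feature_space(X)
        np.testing.assert_allclose(
            space.loadings @ space.loadings.T, np.eye(3), atol=1e-10
        )
        evr = space.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        # scores centred, uncorrelated
        np.testing.assert_allclose(space.scores.mean(axis=0), 0, atol=1e-10)
        cov = np.cov(space.scores.T)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-10)

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(30, 6)) * 0.2 + [2, 5, 0.1, 0.1, 0.08, 0.05]
        a = fit_feature_space(X)
        b = fit_feature_space(X)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        # PC1 loads positively on q21, PC2 on q12, PC3 negatively on v_U
        kept = a.kept.tolist()
        assert a.loadings[0, kept.index(5)] > 0
        assert a.loadings[1, kept.index(4)] > 0
        assert a.loadings[2, kept.index(1)] < 0

    def test_zero_variance_coordinate_dropped_with_warning(self, rng):
        X = rng.normal(size=(10, 6))
        X[:, 2] = 0.1225
        with pytest.warns(RuntimeWarning, match="sigma2_L"):
            space = fit_feature_space(X)
        assert 2 not in space.kept.tolist()

    def test_joint_vL_drop_q21_rise_lands_on_pc1(self):
        """Clusters separated only by lower v_L with higher q21 fall apart
        along PC1, which loads negatively on v_L and positively on q21."""
        X, labels = two_cluster_vectors()
        space = fit_feature_space(X)
        kept = space.kept.tolist()
        assert space.loadings[0, kept.index(5)] > 0.4  # q21 up
        assert space.loadings[0, kept.index(0)] < -0.4  # v_L down
        pc1 = space.scores[:, 0]
        assert pc1[labels == 1].min() > pc1[labels == 0].max()

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            fit_feature_space(np.ones((3, 6)))

    def test_transform_matches_fitted_scores(self, rng):
        X = rng.normal(size=(20, 6)) * 0.3 + [2, 5, 0.1, 0.1, 0.1, 0.1]
        space = fit_feature_space(X)
        np.testing.assert_allclose(space.transform(X), space.scores, atol=1e-10)


class TestSkillAxes:
    def test_centroid_scores_zero_on_all_axes(self, rng):
        X = rng.normal(size=(12, 6)) * 0.2 + [2, 5, 0.1, 0.1, 0.1, 0.1]
        space = fit_feature_space(X)
        centre = skill_axes(space, scores=np.zeros((1, 3)))
        assert (centre.to_numpy() == 0).all()

    def test_energy_and_confidence_are_orthogonal(self, rng):
        X = rng.normal(size=(25, 6)) * 0.3 + [2, 5, 0.1, 0.1, 0.1, 0.1]
        space = fit_feature_space(X)
        axes = skill_axes(space)
        # rotation identity: dot product equals (PC1^2 - PC3^2)/2 summed,
        # and the axis directions themselves are orthogonal unit vectors
        e_dir = np.array([-1, 0, -1]) / np.sqrt(2)
        c_dir = np.array([-1, 0, 1]) / np.sqrt(2)
        assert e_dir @ c_dir == pytest.approx(0.0)
        np.testing.assert_allclose(
            axes["energy"], space.scores @ e_dir, atol=1e-12
        )
        np.testing.assert_allclose(
            axes["confidence"], space.scores @ c_dir, atol=1e-12
        )

    def test_frequent_switchers_score_highest_on_abruptness(self):
        """A latent switching-intensity trait driving q12 and q21 up (and
        the force levels mildly down) dominates the cohort; the
        heaviest switcher sits at the top of the abruptness axis."""
        g = np.random.default_rng(1)
        t = np.linspace(-1, 1, 8)
        coeffs = np.array([-0.3, -0.3, 0.01, 0.01, 0.12, 0.12])
        base = np.array([2.0, 5.0, 0.1, 0.1, 0.15, 0.15])
        X = base + np.outer(t, coeffs)
        X += g.normal(0, 1, X.shape) * (0.05 * np.abs(coeffs))
        space = fit_feature_space(X)
        axes = skill_axes(space)
        assert axes["abruptness"].idxmax() == 7  # the highest-q row


class TestScoreSurface:
    def test_barycentric_average_at_triangle_centre(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        scores = np.array([0.0, 0.0, 3.0])
        bary = pts.mean(axis=0)
        gx, gy, vals = score_surface(pts, scores, grid=(np.array([bary[0]]), np.array([bary[1]])))
        assert vals[0, 0] == pytest.approx(1.0)

    def test_constant_scores_give_constant_surface(self, rng):
        pts = rng.normal(size=(10, 2))
        _, _, vals = score_surface(pts, np.full(10, 2.0), grid=15)
        inside = vals[np.isfinite(vals)]
        np.testing.assert_allclose(inside, 2.0, atol=1e-12)

    def test_matches_barycentric_oracle(self, rng):
        from scipy.spatial import Delaunay

        pts = rng.normal(size=(12, 2))
        scores = rng.uniform(0, 3, 12)
        gx, gy, vals = score_surface(pts, scores, grid=8)
        tri = Delaunay(pts)
        GX, GY = np.meshgrid(gx, gy)
        for i in range(GY.shape[0]):
            for j in range(GX.shape[1]):
                q = np.array([GX[i, j], GY[i, j]])
                s = tri.find_simplex(q)
                if s == -1:
                    assert np.isnan(vals[i, j])
                    continue
                T = tri.transform[s]
                b = T[:2] @ (q - T[2])
                bary = np.append(b, 1 - b.sum())
                expected = bary @ scores[tri.simplices[s]]
                assert vals[i, j] == pytest.approx(expected, abs=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            score_surface(pts, np.arange(4.0))
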