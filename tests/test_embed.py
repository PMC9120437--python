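"""Stress embedding, PCA feature extraction and correlation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dynawass.embed import (
    EmbeddingConfig,
    embed_distances,
    pca_project,
    pearson,
    stress,
)
from dynawass.errors import PreconditionError


def pairwise(points):
    d = points[:, None, :] - points[None, :, :]
    return np.sqrt((d**2).sum(-1))


class TestStress:
    def test_exact_distances_give_zero(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        assert stress(pts, pairwise(pts)) == pytest.approx(0.0, abs=1e-20)

    def test_two_points(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert stress(pts, w) == pytest.approx(1.0)

    def test_matches_term_by_term_summation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 3))
        w = rng.uniform(0.5, 2.0, size=(4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        by_hand = sum(
            (w[i, j] - np.linalg.norm(pts[i] - pts[j])) ** 2 for i in range(4) for j in range(i + 1, 4)
        )
        assert stress(pts, w) == pytest.approx(by_hand, rel=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        w = pairwise(rng.normal(size=(6, 3)))
        from scipy.spatial.transform import Rotation

        moved = pts @ Rotation.random(random_state=0).as_matrix().T + np.array([1.0, -2.0, 0.5])
        reflected = pts * np.array([-1.0, 1.0, 1.0])
        assert stress(moved, w) == pytest.approx(stress(pts, w), rel=1e-10)
        assert stress(reflected, w) == pytest.approx(stress(pts, w), rel=1e-10)

    def test_size_mismatch(self):
        with pytest.raises(PreconditionError):
            stress(np.zeros((3, 2)), np.zeros((4, 4)))


class TestEmbedDistances:
    def test_two_points_realize_distance(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = embed_distances(w, EmbeddingConfig(seed=0, n_restarts=4, sa_steps=200))
        assert np.linalg.norm(res.points[0] - res.points[1]) == pytest.approx(1.0, abs=1e-6)
        assert res.stress <= 1e-10

    def test_planted_points_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3))
        w = pairwise(pts)
        res = embed_distances(w, EmbeddingConfig(seed=1, n_restarts=8))
        assert res.stress <= 1e-8
        assert np.abs(pairwise(res.points) - w).max() <= 1e-3
        assert res.stress == pytest.approx(min(res.restart_losses))

    def test_star_metric_floor_positive_and_matches_multistart(self):
        # center-leaf 1, leaf-leaf 2: needs circumradius 2/sqrt(3) > 1, not realizable
        w = np.ones((4, 4)) * 2.0
        w[0, :] = w[:, 0] = 1.0
        np.fill_diagonal(w, 0.0)
        res = embed_distances(w, EmbeddingConfig(seed=2, n_restarts=8))
        assert res.stress > 1e-3
        floor = min(
            minimize(
                lambda x: stress(x.reshape(4, 3), w),
                np.random.default_rng(s).normal(size=12),
                method="Nelder-Mead",
                options={"maxiter": 20000, "fatol": 1e-14, "xatol": 1e-12},
            ).fun
            for s in range(10)
        )
        assert res.stress == pytest.approx(floor, rel=1e-3)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(PreconditionError):
            embed_distances(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestPCA:
    def test_collinear_points(self):
        t = np.linspace(0, 1, 5)[:, None]
        pts = t * np.array([[1.0, 2.0, -1.0]])
        feat = pca_project(pts)
        assert feat.explained_variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_square_corners_tie(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        feat = pca_project(pts)
        assert feat.explained_variance_fractions[0] == pytest.approx(
            feat.explained_variance_fractions[1]
        )

    def test_eigenvector_recovery_vs_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(200, 3)) * np.sqrt(np.array([9.0, 1.0, 0.01]))
        feat = pca_project(pts)
        ref = PCA(n_components=2).fit(pts)
        for k in range(2):
            dot = abs(np.dot(feat.loadings[:, k], ref.components_[k]))
            assert dot == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(
            feat.explained_variance_fractions, ref.explained_variance_ratio_, rtol=1e-8
        )

    def test_translation_invariance_and_sign_convention(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        a = pca_project(pts, reference_index=0)
        b = pca_project(pts + np.array([10.0, -3.0, 2.0]), reference_index=0)
        np.testing.assert_allclose(a.pc_scores, b.pc_scores, atol=1e-9)
        assert a.pc_scores[0, 0] <= 0  # apo on the negative PC1 side


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(PreconditionError):
            pearson(np.ones(4), np.array([1.0, 2, 3, 4]))
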