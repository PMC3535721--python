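"""LSA, LLE, and Isomap reducers against analytic and planted oracles."""

import numpy as np
import pytest
from scipy.linalg import svd
from scipy.spatial.distance import cdist, pdist

from mirnaclust.reduction import (
    ReducerSpec,
    classical_mds,
    geodesic_distances,
    lle_weights,
    reduce_isomap,
    reduce_lle,
    reduce_lsa,
)


def affine_residual(Y, target):
    """RMS residual of the best affine map Y -> target."""
    A = np.hstack([Y, np.ones((Y.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    return np.sqrt(np.mean((A @ coef - target) ** 2))


class TestLSA:
    def test_exact_rank_reconstruction(self, rng):
        basis = rng.normal(size=(2, 30))
        X = rng.normal(size=(20, 2)) @ basis  # exact rank 2
        Y = reduce_lsa(X, 2)
        # rank-2 projection loses nothing: pairwise distances preserved
        np.testing.assert_allclose(pdist(Y), pdist(X), atol=1e-8)

    def test_full_rank_isometry(self, rng):
        X = rng.normal(size=(12, 8))
        Y = reduce_lsa(X, 8)
        np.testing.assert_allclose(pdist(Y), pdist(X), atol=1e-8)

    def test_reconstruction_error_matches_dense_svd(self, rng):
        X = rng.random(size=(50, 340))
        d = 10
        Y = reduce_lsa(X, d)
        # energy captured by the projection equals the top-d spectrum
        s = svd(X, compute_uv=False)
        np.testing.assert_allclose(
            np.sum(Y**2), np.sum(s[:d] ** 2), rtol=1e-10
        )
        # hence residual energy equals the optimal rank-d error
        np.testing.assert_allclose(
            np.sum(X**2) - np.sum(Y**2), np.sum(s[d:] ** 2), rtol=1e-8
        )

    def test_rank_deficient_warns_and_truncates(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=6))  # rank 1
        with pytest.warns(UserWarning, match="rank"):
            Y = reduce_lsa(X, 3)
        assert Y.shape == (10, 1)

    def test_deterministic_sign(self, rng):
        X = rng.normal(size=(15, 7))
        np.testing.assert_array_equal(reduce_lsa(X, 3), reduce_lsa(X, 3))


class TestLLE:
    def test_weight_rows_sum_to_one(self, rng):
        X = rng.normal(size=(30, 10))
        W = lle_weights(X, k_neighbors=5)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-8)

    def test_embedding_centered(self, rng):
        X = rng.normal(size=(30, 10))
        Y = reduce_lle(X, 2, k_neighbors=6)
        np.testing.assert_allclose(Y.mean(axis=0), 0.0, atol=1e-8)

    def test_planted_plane_recovered_affinely(self, rng):
        # 40 points on a 2-D plane embedded in 340-D
        coords = rng.uniform(size=(40, 2))
        basis = rng.normal(size=(2, 340))
        X = coords @ basis
        Y = reduce_lle(X, 2, k_neighbors=10)
        assert affine_residual(Y, coords - coords.mean(axis=0)) < 1e-2

    def test_duplicate_point_coincides_with_twin(self, rng):
        X = rng.normal(size=(25, 6))
        X = np.vstack([X, X[3]])
        Y = reduce_lle(X, 2, k_neighbors=5)
        np.testing.assert_allclose(Y[-1], Y[3], atol=1e-6)

    def test_needs_enough_points(self, rng):
        with pytest.raises(ValueError):
            reduce_lle(rng.normal(size=(5, 3)), 2, k_neighbors=5)


class TestIsomap:
    def test_points_on_line_reproduce_gaps(self):
        x = np.array([0.0, 1.0, 3.0, 6.0, 10.0])
        X = np.column_stack([x, np.zeros(5)])
        Y = reduce_isomap(X, 1, k_neighbors=2)
        got = np.diff(np.sort(Y[:, 0]))
        expected = np.diff(x)
        # embedding is defined up to sign: accept either orientation
        try:
            np.testing.assert_allclose(got, expected, atol=1e-8)
        except AssertionError:
            np.testing.assert_allclose(got, expected[::-1], atol=1e-8)

    def test_complete_graph_equals_classical_mds(self, rng):
        X = rng.normal(size=(20, 5))
        Y = reduce_isomap(X, 3, k_neighbors=19, metric="euclidean")
        # independent oracle: classical MDS straight on the distances
        D = cdist(X, X)
        n = 20
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(vals)[::-1][:3]
        expected = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        # match up to orthogonal transform: compare pairwise distances
        np.testing.assert_allclose(pdist(Y), pdist(expected), atol=1e-8)

    def test_swiss_roll_geodesics_track_planted_parameters(self, rng):
        n = 300
        t = 1.5 * np.pi * (1 + 2 * rng.uniform(size=n))
        h = 10 * rng.uniform(size=n)
        X = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
        G = geodesic_distances(X, k_neighbors=10, metric="euclidean")
        # arc length along the roll: integral of sqrt(1+t^2)
        s = 0.5 * (t * np.sqrt(1 + t**2) + np.arcsinh(t))
        planted = np.sqrt(
            (s[:, None] - s[None, :]) ** 2 + (h[:, None] - h[None, :]) ** 2
        )
        iu = np.triu_indices(n, 1)
        r = np.corrcoef(G[iu], planted[iu])[0, 1]
        assert r >= 0.99

    def test_disconnected_graph_bridged(self, rng):
        X = np.vstack([
            rng.normal(size=(10, 3)),
            rng.normal(size=(10, 3)) + 100.0,
        ])
        Y = reduce_isomap(X, 2, k_neighbors=3)
        assert Y.shape == (20, 2)
        assert np.isfinite(Y).all()

    def test_deterministic(self, rng):
        X = rng.normal(size=(25, 6))
        np.testing.assert_array_equal(
            reduce_isomap(X, 3, 5), reduce_isomap(X, 3, 5)
        )

    def test_cross_check_against_sklearn(self, rng):
        """Independent implementation check (euclidean neighbors)."""
        from sklearn.manifold import Isomap as SkIsomap

        X = rng.normal(size=(60, 8))
        ours = reduce_isomap(X, 3, k_neighbors=8, metric="euclidean")
        theirs = SkIsomap(n_neighbors=8, n_components=3).fit_transform(X)
        np.testing.assert_allclose(pdist(ours), pdist(theirs), atol=1e-8)


class TestReducerSpec:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ReducerSpec(method="tsne")

    def test_small_k_warns(self):
        with pytest.warns(UserWarning, match="k_neighbors"):
            ReducerSpec(method="isomap", d=150, k_neighbors=2)


def test_mds_recovers_configuration(rng):
    X = rng.normal(size=(15, 4))
    D = cdist(X, X)
    Y = classical_mds(D, 4)
    np.testing.assert_allclose(pdist(Y), pdist(X), atol=1e-8)
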