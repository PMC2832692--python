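"""Distances, PCA and complete-linkage clustering against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import nullvec as nv
from nullvec.relate import DistanceMatrix, to_newick


def brute_force_complete_linkage(ids, d):
    """Exhaustive agglomerator: recompute every cluster-pair maximum each step."""
    clusters = {i: frozenset([i]) for i in range(len(ids))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d[i][j] for i in clusters[a] for j in clusters[b])
            key = (h, tuple(sorted((min(ids[i] for i in clusters[a]),
                                    min(ids[i] for i in clusters[b])))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (h, _), a, b = best[0], best[1], best[2]
        heights.append(h)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return heights


class TestEuclidean:
    def test_identity_symmetry_345(self, rng):
        u = nv.FeatureVector("u", rng.standard_normal(60))
        w = nv.FeatureVector("w", u.components.copy())
        assert nv.euclidean_distance(u, w) == 0.0
        delta = np.zeros(60)
        delta[0], delta[1] = 3.0, 4.0
        v = nv.FeatureVector("v", u.components + delta)
        assert nv.euclidean_distance(u, v) == pytest.approx(5.0)
        assert nv.euclidean_distance(u, v) == nv.euclidean_distance(v, u)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            nv.euclidean_distance(np.zeros(60), np.zeros(12))


class TestDistanceMatrix:
    def test_identical_vectors_all_zero(self):
        X = np.ones((3, 6))
        dm = nv.distance_matrix((list("abc"), X))
        np.testing.assert_array_equal(dm.d, np.zeros((3, 3)))

    def test_matches_pairwise_calls(self, rng):
        X = rng.standard_normal((6, 10))
        dm = nv.distance_matrix(([f"s{i}" for i in range(6)], X))
        for i in range(6):
            for j in range(6):
                assert dm.d[i, j] == pytest.approx(nv.euclidean_distance(X[i], X[j]))

    def test_triangle_inequality(self, rng):
        X = rng.standard_normal((50, 8))
        d = nv.distance_matrix(([str(i) for i in range(50)], X)).d
        for i, j, k in itertools.combinations(range(20), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_too_few_vectors(self):
        with pytest.raises(ValueError):
            nv.distance_matrix((["a"], np.zeros((1, 3))))


class TestPCA:
    def test_matches_dense_eigendecomposition(self, rng):
        """Scores/loadings agree with a covariance eigensolver to 1e-8 up to sign."""
        X = rng.standard_normal((20, 6))
        res = nv.pca_project(([str(i) for i in range(20)], X), k=6)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(res.explained_variance, evals, atol=1e-8)
        for j in range(6):
            dot = abs(res.loadings[:, j] @ evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(np.abs(Xc @ evecs[:, j]), np.abs(res.scores[:, j]), atol=1e-8)

    def test_collinear_data_is_rank_one(self, rng):
        w = rng.standard_normal(5)
        t = rng.standard_normal(15)
        X = np.outer(t, w)
        res = nv.pca_project(([str(i) for i in range(15)], X), k=2)
        assert res.explained_variance[1] == pytest.approx(0.0, abs=1e-10)
        assert res.explained_variance[0] == pytest.approx(
            np.sum(np.var(X, axis=0, ddof=1)), rel=1e-10)

    def test_explained_variance_conserves_total(self, rng):
        X = rng.standard_normal((12, 5))
        res = nv.pca_project(([str(i) for i in range(12)], X), k=5)
        assert np.sum(res.explained_variance) == pytest.approx(
            np.sum(np.var(X, axis=0, ddof=1)))

    def test_loadings_orthonormal_scores_centered_uncorrelated(self, rng):
        X = rng.standard_normal((30, 8))
        res = nv.pca_project(([str(i) for i in range(30)], X), k=4)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-8)
        cov = np.cov(res.scores, rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-8)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_component_reordering_invariance(self, rng):
        X = rng.standard_normal((15, 9))
        perm = rng.permutation(9)
        a = nv.pca_project(([str(i) for i in range(15)], X), k=3)
        b = nv.pca_project(([str(i) for i in range(15)], X[:, perm]), k=3)
        np.testing.assert_allclose(np.abs(a.scores), np.abs(b.scores), atol=1e-8)

    def test_zero_variance_warns(self):
        X = np.ones((4, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = nv.pca_project((list("abcd"), X), k=2)
        np.testing.assert_array_equal(res.scores, 0)

    def test_k_out_of_range(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError):
            nv.pca_project((list("abcde"), X), k=4)


class TestCompleteLinkage:
    def test_three_leaf_hand_trace(self):
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        tree = nv.complete_linkage_cluster(DistanceMatrix(("a", "b", "c"), d))
        assert len(tree.merges) == 2
        assert tree.merges[0][:2] == (0, 1) and tree.merges[0][2] == pytest.approx(1.0)
        assert tree.merges[1][2] == pytest.approx(5.0)  # max(4, 5)

    def test_all_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        ids = ("d", "c", "b", "a")
        t1 = nv.complete_linkage_cluster(DistanceMatrix(ids, d))
        t2 = nv.complete_linkage_cluster(DistanceMatrix(ids, d))
        assert t1.merges == t2.merges
        assert all(h == pytest.approx(1.0) for _, _, h in t1.merges)
        # lexicographic tie-break: 'a' (leaf 3) and 'b' (leaf 2) merge first
        assert set(t1.merges[0][:2]) == {2, 3}

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_brute_force_oracle(self, n, rng):
        for _ in range(10):
            X = rng.standard_normal((n, 4))
            dm = nv.distance_matrix(([f"s{i}" for i in range(n)], X))
            tree = nv.complete_linkage_cluster(dm)
            ours = [h for _, _, h in tree.merges]
            oracle = brute_force_complete_linkage(dm.ids, dm.d)
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_matches_scipy_heights(self, rng):
        X = rng.standard_normal((25, 6))
        dm = nv.distance_matrix(([f"s{i:02d}" for i in range(25)], X))
        Z = linkage(squareform(dm.d, checks=False), method="complete")
        ours = sorted(h for _, _, h in nv.complete_linkage_cluster(dm).merges)
        np.testing.assert_allclose(ours, sorted(Z[:, 2]), atol=1e-9)

    def test_heights_nondecreasing(self, rng):
        X = rng.standard_normal((15, 5))
        dm = nv.distance_matrix(([str(i) for i in range(15)], X))
        heights = [h for _, _, h in nv.complete_linkage_cluster(dm).merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_duplicate_vector_merges_at_zero_first(self, rng):
        X = rng.standard_normal((5, 4))
        X = np.vstack([X, X[2]])
        dm = nv.distance_matrix(([f"s{i}" for i in range(6)], X))
        tree = nv.complete_linkage_cluster(dm)
        a, b, h = tree.merges[0]
        assert h == pytest.approx(0.0) and {a, b} == {2, 5}

    def test_nan_rejected(self):
        d = np.zeros((2, 2))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(("a", "b"), d)

    def test_cut_recovers_two_blocks(self):
        d = np.array([
            [0, 1, 9, 9],
            [1, 0, 9, 9],
            [9, 9, 0, 1],
            [9, 9, 1, 0],
        ], dtype=float)
        tree = nv.complete_linkage_cluster(DistanceMatrix(tuple("abcd"), d))
        labels = tree.cut(2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]


class TestNewick:
    def test_two_leaves(self):
        tree = nv.Dendrogram(("a", "b"), ((0, 1, 2.0),))
        assert to_newick(tree) == "(a:2,b:2);"

    def test_three_leaf_hand_trace(self):
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        tree = nv.complete_linkage_cluster(DistanceMatrix(("a", "b", "c"), d))
        assert to_newick(tree) == "((a:1,b:1):4,c:5);"

    def test_round_trip_preserves_topology_and_heights(self, rng):
        import io

        from Bio import Phylo

        X = rng.standard_normal((8, 5))
        dm = nv.distance_matrix(([f"s{i}" for i in range(8)], X))
        tree = nv.complete_linkage_cluster(dm)
        parsed = Phylo.read(io.StringIO(to_newick(tree)), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(dm.ids)
        root_height = tree.merges[-1][2]
        for leaf in parsed.get_terminals():
            assert parsed.distance(leaf) == pytest.approx(root_height, abs=1e-9)
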