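import numpy as np
import pytest
from sklearn.cluster import SpectralClustering

from bltsa import local_geometry as lg
from bltsa.branching import (
    BranchLabeling,
    assign_branching_cells,
    branch_distance,
    cluster_nonbranching,
    gaussian_affinity,
    redistribute_neighborhoods,
)


def star(angles, n=40, t0=0.5, t1=2.0):
    t = np.linspace(t0, t1, n)
    return np.hstack(
        [np.vstack([t * np.cos(a), t * np.sin(a)]) for a in angles]
    )


class TestGaussianAffinity:
    def test_line_hand_computation(self):
        X = np.array([[0.0, 1.0, 2.0], [0, 0, 0]])
        A = gaussian_affinity(X)
        # pairwise distances {1, 1, 2} -> median bandwidth 1
        assert A[0, 2] == pytest.approx(np.exp(-2.0))
        assert A[0, 1] == pytest.approx(np.exp(-0.5))

    def test_two_points_at_bandwidth_distance(self):
        X = np.array([[0.0, 1.0], [0, 0]])  # sigma = 1 = their distance
        A = gaussian_affinity(X)
        assert A[0, 1] == pytest.approx(np.exp(-0.5))

    def test_kernel_properties(self, rng):
        X = rng.normal(size=(2, 15))
        A = gaussian_affinity(X)
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_array_equal(np.diag(A), 0.0)
        off = A[~np.eye(15, dtype=bool)]
        assert np.all((off > 0) & (off <= 1))

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError):
            gaussian_affinity(np.zeros((2, 6)))


class TestClusterNonbranching:
    def test_two_separated_segments(self):
        t = np.linspace(0, 1, 50)
        X = np.hstack(
            [np.vstack([t, np.zeros(50)]), np.vstack([t, np.full(50, 5.0)])]
        )
        lab = cluster_nonbranching(X, np.arange(100), range(2, 9), seed=0)
        assert lab.n_branches == 2
        assert len(set(lab.labels[:50])) == 1
        assert len(set(lab.labels[50:])) == 1
        assert lab.labels[0] != lab.labels[50]

    def test_agrees_with_sklearn_spectral_clustering(self):
        """Independent cross-check of the spectral recipe on a clean
        two-cluster instance."""
        t = np.linspace(0, 1, 30)
        X = np.hstack(
            [np.vstack([t, np.zeros(30)]), np.vstack([t, np.full(30, 4.0)])]
        )
        lab = cluster_nonbranching(X, np.arange(60), [2], seed=0)
        A = gaussian_affinity(X)
        ref = SpectralClustering(
            n_clusters=2, affinity="precomputed", random_state=0
        ).fit_predict(A)
        same = (lab.labels == lab.labels[0]) == (ref == ref[0])
        assert same.all()

    def test_four_armed_star_recovered(self):
        X = star([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        lab = cluster_nonbranching(X, np.arange(160), range(2, 9), seed=0)
        assert lab.n_branches == 4
        truth = np.repeat(np.arange(4), 40)
        for b in range(4):
            assert len(set(lab.labels[truth == b])) == 1

    def test_duplicating_points_keeps_branch_count(self):
        t = np.linspace(0, 1, 50)
        X = np.hstack(
            [np.vstack([t, np.zeros(50)]), np.vstack([t, np.full(50, 5.0)])]
        )
        X2 = np.hstack([X, X])
        l1 = cluster_nonbranching(X, np.arange(100), range(2, 9), seed=0)
        l2 = cluster_nonbranching(X2, np.arange(200), range(2, 9), seed=0)
        assert l1.n_branches == l2.n_branches


class TestYShapedToy:
    """Noiseless Y with arms 120 degrees apart: the tip/junction detectors
    and the clustering should recover the true structure exactly."""

    @pytest.fixture(scope="class")
    def ytoy(self):
        t = np.linspace(0, 1.5, 60)
        angles = [np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 - 2 * np.pi / 3]
        X = np.hstack(
            [np.vstack([t * np.cos(a), t * np.sin(a)]) for a in angles]
        )
        nbs = lg.knn_neighborhoods(X, 20)
        models = [
            lg.fit_local_tangent(X, Ni, 1, cell_index=i)
            for i, Ni in enumerate(nbs)
        ]
        return X, nbs, models

    def test_top_nonlinearity_at_junction(self, ytoy):
        X, nbs, models = ytoy
        nonlin = np.array([lg.nonlinearity_score(m) for m in models])
        top = int(np.argmax(nonlin))
        assert top % 60 <= 10  # within k/2 arc steps of the junction

    def test_endpoints_are_tips(self, ytoy):
        X, nbs, models = ytoy
        nonlin = np.array([lg.nonlinearity_score(m) for m in models])
        bmask, _ = lg.identify_branching_cells(nonlin)
        cons = np.array(
            [lg.consistency_score(X, i, nbs[i], norm="pairs") for i in range(180)]
        )
        tips = lg.identify_tip_cells(cons, bmask, 0.9, k=20, norm="pairs")
        assert set(np.flatnonzero(tips)) == {59, 119, 179}


class TestBranchDistance:
    def test_orthogonal_offset_gives_tangent_distance(self):
        # straight horizontal branch; query offset vertically by 0.5
        X = np.zeros((2, 11))
        X[0, :10] = np.arange(10.0)
        X[:, 10] = [0.0, 0.5]
        models = {
            j: lg.fit_local_tangent(X, np.arange(10), 1, cell_index=j)
            for j in range(10)
        }
        d = branch_distance(X, models, 10, np.arange(1), n_anchor=1)
        # anchor 0 at (0,0): tangent residual 0.5, euclidean 0.5
        assert d == pytest.approx(0.5)

    def test_point_on_tangent_line_has_zero_tangent_term(self):
        X = np.zeros((2, 11))
        X[0, :10] = np.arange(10.0)
        X[:, 10] = [12.0, 0.0]  # on the branch line, beyond its end
        models = {
            j: lg.fit_local_tangent(X, np.arange(10), 1, cell_index=j)
            for j in range(10)
        }
        d = branch_distance(X, models, 10, np.array([9]), n_anchor=1)
        # tangent term 0, euclidean term 3 -> average 1.5
        assert d == pytest.approx(1.5)

    def test_cross_toy_matches_segment_distance_oracle(self, rng):
        # two orthogonal straight arms; junction-adjacent queries pick the
        # branch minimising true point-to-segment distance
        t = np.linspace(0.5, 3.0, 40)
        armx = np.vstack([t, np.zeros(40)])
        army = np.vstack([np.zeros(40), t])
        X = np.hstack([armx, army])
        nbs = lg.knn_neighborhoods(X, 10)
        models = [
            lg.fit_local_tangent(X, Ni, 1, cell_index=i)
            for i, Ni in enumerate(nbs)
        ]
        queries = rng.uniform(0.3, 1.0, size=(2, 12))
        Xq = np.hstack([X, queries])
        models = {i: m for i, m in enumerate(models)}
        for q in range(80, 92):
            d1 = branch_distance(Xq, models, q, np.arange(40), n_anchor=5)
            d2 = branch_distance(Xq, models, q, np.arange(40, 80), n_anchor=5)
            chosen = 0 if d1 < d2 else 1
            # oracle: distance to the two segments
            px, py = Xq[:, q]
            seg1 = abs(py) if 0.5 <= px <= 3 else np.hypot(px - 0.5, py)
            seg2 = abs(px) if 0.5 <= py <= 3 else np.hypot(px, py - 0.5)
            assert chosen == (0 if seg1 < seg2 else 1)


class TestAssignBranchingCells:
    def test_no_branching_cells_is_identity(self, rng):
        X = rng.normal(size=(2, 30))
        labels = rng.integers(0, 2, 30)
        lab = BranchLabeling(2, labels.copy(), root_branch=0)
        models = {}
        out = assign_branching_cells(X, models, lab, np.array([], dtype=int),
                                     n_anchor=5)
        np.testing.assert_array_equal(out.labels, labels)
        assert out.assignment_order == []

    def test_tangent_term_breaks_euclidean_tie(self):
        # horizontal arm and vertical arm; query equidistant from both in
        # Euclidean terms but aligned with the horizontal arm
        t = np.linspace(1.0, 3.0, 30)
        armx = np.vstack([t, np.zeros(30)])
        army = np.vstack([np.zeros(30), t])
        query = np.array([[0.70711], [0.70711]]) * 1.0  # equidistant corner
        # move query onto the x-axis direction: (0.9, 0.0) is distance 0.1
        # from armx's closest point (1,0) and sqrt(0.81+..) from army
        query = np.array([[0.9], [0.0]])
        X = np.hstack([armx, army, query])
        labels = np.full(61, -1)
        labels[:30] = 0
        labels[30:60] = 1
        nbs = lg.knn_neighborhoods(X, 8)
        models = [
            lg.fit_local_tangent(X, Ni, 1, cell_index=i)
            for i, Ni in enumerate(nbs)
        ]
        lab = BranchLabeling(2, labels, root_branch=0)
        out = assign_branching_cells(X, models, lab, np.array([60]),
                                     n_anchor=5, neighborhoods=nbs)
        assert out.labels[60] == 0
        assert out.assignment_order == [(60, 0)]

    def test_completion_and_determinism(self, rng):
        X = rng.normal(size=(2, 60))
        labels = np.full(60, -1)
        labels[:20] = 0
        labels[20:40] = 1
        branching = np.arange(40, 60)
        nbs = lg.knn_neighborhoods(X, 8)
        models = [
            lg.fit_local_tangent(X, Ni, 1, cell_index=i)
            for i, Ni in enumerate(nbs)
        ]
        runs = []
        for _ in range(2):
            lab = BranchLabeling(2, labels.copy(), root_branch=0)
            out = assign_branching_cells(
                X, list(models), lab, branching, n_anchor=5,
                neighborhoods=[a.copy() for a in nbs],
            )
            runs.append(out)
        assert runs[0].is_complete()
        assert len(runs[0].assignment_order) == 20
        np.testing.assert_array_equal(runs[0].labels, runs[1].labels)
        assert runs[0].assignment_order == runs[1].assignment_order


class TestRedistributeNeighborhoods:
    @pytest.fixture()
    def labeled_star(self):
        # root arm along -x, two branch arms; well separated
        t = np.linspace(0.2, 3.0, 50)
        root = np.vstack([-t[::-1], np.zeros(50)])
        b1 = np.vstack([t, t])
        b2 = np.vstack([t, -t])
        X = np.hstack([root, b1, b2])
        labels = np.repeat([0, 1, 2], 50)
        return X, BranchLabeling(3, labels, root_branch=0)

    def test_root_branch_pool_is_root_only(self, labeled_star):
        X, lab = labeled_star
        nbs, chosen = redistribute_neighborhoods(X, lab, (10, 20))
        for i in range(50):  # root cells
            assert set(lab.labels[nbs[i]]) == {0}

    def test_no_foreign_branch_in_any_neighborhood(self, labeled_star):
        X, lab = labeled_star
        nbs, _ = redistribute_neighborhoods(X, lab, (10, 20))
        for i in range(150):
            allowed = {lab.labels[i], 0}
            assert set(lab.labels[nbs[i]]) <= allowed
            assert i in nbs[i]

    def test_far_cells_match_plain_knn(self, labeled_star):
        X, lab = labeled_star
        nbs, chosen = redistribute_neighborhoods(X, lab, (10, 20))
        plain = lg.knn_neighborhoods(X, 20)
        # the outermost cell of branch 1 is surrounded only by branch-1 cells
        i = 99
        assert set(nbs[i]) <= set(plain[i]) | set(nbs[i])
        assert set(lab.labels[nbs[i]]) == {1}

    def test_incomplete_labeling_rejected(self, labeled_star):
        X, lab = labeled_star
        lab.labels = lab.labels.copy()
        lab.labels[0] = -1
        with pytest.raises(ValueError):
            redistribute_neighborhoods(X, lab, (10, 20))
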