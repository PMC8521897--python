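import numpy as np
import pytest

from apbnrr.adaptation import (AdaptationConfig, MetricField, adapt_mesh,
                               build_metric, centered_mvee, knn_distance,
                               metric_edge_lengths, points_per_vertex_cell)
from apbnrr.mesher import build_mesh

AXIS_POINTS = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]])


class TestKnnDistance:
    def test_kth_distance_on_a_line_of_points(self):
        points = np.array([[d, 0.0, 0.0] for d in (1, 2, 3, 4, 5)])
        d3 = knn_distance(np.zeros((1, 3)), points, k=3)
        assert np.isclose(d3[0], 3.0)

    def test_coincident_point_gives_zero_for_k1(self):
        d = knn_distance(np.array([[1.0, 2.0, 3.0]]), np.array([[1.0, 2.0, 3.0]]), 1)
        assert d[0] == 0.0

    def test_matches_full_sort_brute_force(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(1000, 3))
        verts = rng.normal(size=(50, 3))
        d = knn_distance(verts, points, k=10)
        brute = np.sort(np.linalg.norm(verts[:, None] - points[None], axis=2), axis=1)[:, 9]
        assert np.allclose(d, brute, atol=1e-12)

    def test_k_beyond_point_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_distance(np.zeros((1, 3)), np.zeros((3, 3)), k=5)


class TestCenteredMvee:
    def test_axis_points_give_the_unit_sphere(self):
        M = centered_mvee(np.zeros(3), AXIS_POINTS)
        assert np.allclose(M, np.eye(3), atol=1e-2)

    def test_scaling_law(self):
        M = centered_mvee(np.zeros(3), 2.0 * AXIS_POINTS)
        assert np.allclose(M, np.eye(3) / 4.0, atol=5e-3)

    @pytest.mark.parametrize("trial", range(10))
    def test_enclosure_within_tolerance_on_random_sets(self, trial):
        rng = np.random.default_rng(trial)
        pts = rng.normal(size=(20, 3)) * np.array([3.0, 1.0, 0.5])
        center = rng.normal(scale=0.2, size=3)
        M = centered_mvee(center, pts + center, eps=1e-3)
        q = np.einsum("ij,jk,ik->i", pts, M, pts)
        assert q.max() <= 1.0 + 2e-3
        assert np.linalg.eigvalsh(M).min() > 0

    def test_beats_randomized_enclosing_ellipsoid_search(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(20, 3))
        M = centered_mvee(np.zeros(3), pts, eps=1e-3)
        vol = 1.0 / np.sqrt(np.linalg.det(M))
        best = np.inf
        for _ in range(10000):
            A = rng.normal(size=(3, 3))
            S = A @ A.T + 1e-3 * np.eye(3)
            S = S / np.einsum("ij,jk,ik->i", pts, S, pts).max()
            best = min(best, 1.0 / np.sqrt(np.linalg.det(S)))
        assert vol <= best * (1 + 2e-3)

    def test_degenerate_coplanar_points_regularized(self):
        pts = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]])
        M = centered_mvee(np.zeros(3), pts, min_axis=0.05)
        w = np.linalg.eigvalsh(M)
        assert w.min() > 0  # SPD despite zero extent along z


class TestBuildMetric:
    def test_isotropic_formula(self, cube_labels):
        mesh = build_mesh(cube_labels, 5.0)
        points = mesh.vertices[0][None] + np.array([[2.0, 0.0, 0.0]])
        metric = build_metric(mesh, points, AdaptationConfig(k=1, mode="isotropic"))
        assert np.allclose(metric.tensors[0], np.eye(3) / 4.0, atol=1e-9)

    def test_inflation_scales_eigenvalues_inverse_square(self, cube_labels):
        mesh = build_mesh(cube_labels, 5.0)
        rng = np.random.default_rng(1)
        pts = rng.uniform(4, 20, size=(60, 3))
        base = build_metric(mesh, pts, AdaptationConfig(k=8, a=1.0, mode="anisotropic"))
        inflated = build_metric(mesh, pts, AdaptationConfig(k=8, a=2.0, mode="anisotropic"))
        assert np.allclose(inflated.tensors, base.tensors / 4.0, atol=1e-9)

    def test_inflated_ellipsoids_nest(self, cube_labels):
        mesh = build_mesh(cube_labels, 5.0)
        rng = np.random.default_rng(2)
        pts = rng.uniform(4, 20, size=(60, 3))
        m1 = build_metric(mesh, pts, AdaptationConfig(k=8, a=1.0, mode="anisotropic"))
        m15 = build_metric(mesh, pts, AdaptationConfig(k=8, a=1.5, mode="anisotropic"))
        # (x^T M15 x <= 1) region contains (x^T M1 x <= 1): M1 - M15 is PSD
        for d in np.linalg.eigvalsh(m1.tensors - m15.tensors):
            assert d.min() > -1e-12

    def test_spd_preserved_under_interpolation(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(2, 3, 3))
        Ma, Mb = A @ A.T + 0.1 * np.eye(3), B @ B.T + 0.1 * np.eye(3)
        for t in np.linspace(0, 1, 7):
            assert np.linalg.eigvalsh(t * Ma + (1 - t) * Mb).min() > 0


class TestAdaptMesh:
    def test_coarse_metric_leaves_mesh_unchanged(self, cube_labels):
        mesh = build_mesh(cube_labels, 5.0)
        metric = MetricField(np.tile(np.eye(3) / 1e6, (mesh.n_vertices, 1, 1)))
        out, _ = adapt_mesh(mesh, metric)
        assert out.n_tets == mesh.n_tets

    def test_fine_uniform_metric_splits_every_original_edge(self, cube_labels):
        mesh = build_mesh(cube_labels, 5.0)
        lengths = np.linalg.norm(
            mesh.vertices[mesh.edges()[:, 0]] - mesh.vertices[mesh.edges()[:, 1]], axis=1)
        h = lengths.min() / 2.0  # target spacing = half the shortest edge
        metric = MetricField(np.tile(np.eye(3) / h**2, (mesh.n_vertices, 1, 1)))
        out, m2 = adapt_mesh(mesh, metric, max_factor=60, max_passes=200)
        assert out.n_tets > mesh.n_tets
        # every original edge exceeded the metric bound, so none survives
        original = {tuple(e) for e in mesh.edges()}
        surviving = {tuple(e) for e in out.edges()}
        assert not (original & surviving)

    def test_adapted_mesh_remains_valid(self, cube_labels):
        mesh = build_mesh(cube_labels, 5.0)
        rng = np.random.default_rng(4)
        pts = np.concatenate([rng.normal((8, 8, 8), 1.5, size=(80, 3)),
                              rng.normal((18, 18, 18), 1.5, size=(80, 3))])
        metric = build_metric(mesh, np.clip(pts, 3, 21),
                              AdaptationConfig(k=20, mode="isotropic"))
        out, _ = adapt_mesh(mesh, metric)
        assert (out.volumes() > 0).all()
        assert set(np.unique(out.tissue)) <= {1, 2}
        assert np.isclose(np.abs(out.volumes()).sum(), np.abs(mesh.volumes()).sum(),
                          rtol=1e-9)

    def test_refinement_equidistributes_clustered_points(self, cube_labels):
        mesh = build_mesh(cube_labels, 4.0)
        rng = np.random.default_rng(1)
        clusters = np.concatenate([
            rng.normal(loc, 1.2, size=(120, 3))
            for loc in [(6, 6, 6), (16, 15, 14), (10, 18, 7)]])
        clusters = np.clip(clusters, 3, 21)
        cfg = AdaptationConfig(k=min(30, len(clusters) // 2), mode="isotropic")
        metric = build_metric(mesh, clusters, cfg)
        adapted, _ = adapt_mesh(mesh, metric)
        before = points_per_vertex_cell(mesh, clusters)
        after = points_per_vertex_cell(adapted, clusters)
        assert after.var() < before.var()
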