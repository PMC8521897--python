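import numpy as np
import pytest
from scipy import sparse

from apbnrr.blockmatch import SparseDisplacementField
from apbnrr.core import PARENCHYMA, TUMOR, ImageVolume, RegistrationConfig
from apbnrr.fem import (MaterialTable, assemble_coupling, assemble_stiffness,
                        dense_field, invert_field, normalized_stiffness,
                        register_pbnrr, solve_approximation, warp_image)
from apbnrr.mesher import TetLocator, TetMesh, build_mesh

UNIT_TET = TetMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
                   [[0, 1, 2, 3]], [PARENCHYMA])
MATS = MaterialTable({PARENCHYMA: (2100.0, 0.45), TUMOR: (21000.0, 0.45)})


def _dense_stiffness_oracle(mesh, materials):
    """Independent dense assembly via numerical differentiation of the energy.

    Elastic energy of a P1 tet mesh is quadratic, E(u) = 1/2 u^T K u, so
    K_ij = d2E/du_i du_j computed by central differences on the exact
    per-element energy integrand.
    """
    def energy(u):
        u = u.reshape(-1, 3)
        total = 0.0
        coords = mesh.tet_coords()
        for t in range(mesh.n_tets):
            X = coords[t]
            A = np.hstack([np.ones((4, 1)), X])
            grads = np.linalg.inv(A)[1:, :].T  # (4 nodes, 3)
            F = np.zeros((3, 3))
            for node in range(4):
                F += np.outer(u[mesh.tets[t, node]], grads[node])
            eps = 0.5 * (F + F.T)
            E, nu = materials[int(mesh.tissue[t])]
            lam = E * nu / ((1 + nu) * (1 - 2 * nu))
            mu = E / (2 * (1 + nu))
            vol = abs(np.linalg.det(X[1:] - X[0]) / 6.0)
            total += vol * (0.5 * lam * np.trace(eps) ** 2 + mu * (eps * eps).sum())
        return total

    n = 3 * mesh.n_vertices
    K = np.zeros((n, n))
    h = 1e-4
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            kij = (energy(ei + ej) - energy(ei - ej) - energy(-ei + ej)
                   + energy(-ei - ej)) / (4 * h * h)
            K[i, j] = K[j, i] = kij
    return K


class TestAssembleStiffness:
    def test_rigid_translations_in_null_space(self):
        K = assemble_stiffness(UNIT_TET, MATS)
        for axis in range(3):
            t = np.zeros((4, 3))
            t[:, axis] = 1.0
            assert np.abs(K @ t.ravel()).max() < 1e-8

    def test_linearity_in_youngs_modulus(self):
        K1 = assemble_stiffness(UNIT_TET, MaterialTable({PARENCHYMA: (1000.0, 0.3)}))
        K2 = assemble_stiffness(UNIT_TET, MaterialTable({PARENCHYMA: (2000.0, 0.3)}))
        assert np.allclose(K2.toarray(), 2 * K1.toarray(), rtol=1e-12)

    def test_symmetric_positive_semidefinite(self):
        mesh = TetMesh(
            np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2], [2, 2, 2]]),
            [[0, 1, 2, 3], [1, 2, 3, 4]], [PARENCHYMA, TUMOR])
        K = assemble_stiffness(mesh, MATS).toarray()
        assert np.allclose(K, K.T, atol=1e-9)
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-6 * w.max()

    def test_matches_independent_dense_energy_assembly(self):
        mesh = TetMesh(
            np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0, 0, 0.9], [1.1, 1.3, 1.2]]),
            [[0, 1, 2, 3], [1, 2, 3, 4]], [PARENCHYMA, TUMOR])
        K = assemble_stiffness(mesh, MATS).toarray()
        K_oracle = _dense_stiffness_oracle(mesh, MATS)
        assert np.allclose(K, K_oracle, rtol=1e-4, atol=1e-3 * np.abs(K_oracle).max())

    def test_degenerate_tet_rejected(self):
        flat = TetMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]),
                       [[0, 1, 2, 3]], [PARENCHYMA])
        with pytest.raises(ValueError, match="degenerate"):
            assemble_stiffness(flat, MATS)


def _field_at(points_mm, d=None, scores=None):
    n = len(points_mm)
    return SparseDisplacementField(
        centers_vox=np.zeros((n, 3), dtype=int),
        centers_mm=np.asarray(points_mm, dtype=float),
        displacements_mm=np.zeros((n, 3)) if d is None else np.asarray(d, float),
        scores=np.ones(n) if scores is None else np.asarray(scores, float),
        zero_correspondence=np.zeros(n, dtype=bool),
        active=np.ones(n, dtype=bool),
    )


class TestAssembleCoupling:
    def test_block_at_vertex_gives_unit_indicator_row(self):
        field = _field_at([UNIT_TET.vertices[2]])
        H, S, D, used, _ = assemble_coupling(UNIT_TET, field)
        row = np.asarray(H[0].todense()).ravel()
        assert np.isclose(row[3 * 2 + 0], 1.0, atol=1e-9)
        assert np.isclose(np.abs(row).sum(), 1.0, atol=1e-9)

    def test_block_at_centroid_gives_quarter_weights(self):
        field = _field_at([UNIT_TET.vertices.mean(axis=0)])
        H, *_ = assemble_coupling(UNIT_TET, field)
        row = np.asarray(H[0].todense()).ravel()
        assert np.allclose(row[row != 0], 0.25, atol=1e-9)

    def test_interpolation_reproduces_global_linear_fields(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        pts = mesh.centroids()[::11]
        field = _field_at(pts)
        H, _, _, used, _ = assemble_coupling(mesh, field, TetLocator(mesh))
        nodal = mesh.vertices @ A.T + b
        interp = (H @ nodal.ravel()).reshape(-1, 3)
        assert np.allclose(interp, pts[: len(used)] @ A.T + b, atol=1e-8)

    def test_outside_and_flagged_blocks_excluded(self):
        field = _field_at([[0.2, 0.2, 0.2], [10.0, 10.0, 10.0], [0.3, 0.3, 0.3]])
        field.zero_correspondence[2] = True
        H, _, _, used, excluded = assemble_coupling(UNIT_TET, field)
        assert list(used) == [0]
        assert set(excluded) == {1, 2}

    def test_no_usable_blocks_rejected(self):
        field = _field_at([[0.2, 0.2, 0.2]])
        field.active[0] = False
        with pytest.raises(ValueError, match="usable"):
            assemble_coupling(UNIT_TET, field)


class TestSolveApproximation:
    def _system(self, mesh, pts, d):
        K = normalized_stiffness(assemble_stiffness(mesh, MATS), mesh, 2100.0)
        field = _field_at(pts, d)
        H, S, D, *_ = assemble_coupling(mesh, field, TetLocator(mesh))
        return K, H, S, D

    def test_zero_data_gives_zero_solution(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        pts = mesh.centroids()[::13]
        K, H, S, D = self._system(mesh, pts, np.zeros((len(pts), 3)))
        U = solve_approximation(K, H, S, D, 1.0)
        assert np.abs(U).max() < 1e-10

    def test_matches_dense_normal_equations(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(1)
        pts = mesh.centroids()[::13]
        d = rng.normal(scale=2.0, size=(len(pts), 3))
        K, H, S, D = self._system(mesh, pts, d)
        U = solve_approximation(K, H, S, D, 1.0)
        A = (K + H.T @ S @ H).toarray()
        U_dense = np.linalg.solve(A, H.T @ (S @ D)).reshape(-1, 3)
        assert np.linalg.norm(U - U_dense) <= 1e-8 * max(np.linalg.norm(U_dense), 1)

    def test_constant_translation_data_recovered_exactly(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        pts = mesh.centroids()[::13]
        t = np.array([1.5, -2.0, 0.5])
        K, H, S, D = self._system(mesh, pts, np.tile(t, (len(pts), 1)))
        U = solve_approximation(K, H, S, D, 1.0)
        assert np.allclose(U, t, atol=1e-8)


class TestRegisterPBNRR:
    def _consistent_field(self, mesh, rng, n=120, outliers=0):
        ids = rng.choice(mesh.n_tets, size=n, replace=False)
        pts = mesh.centroids()[ids]
        t = np.array([2.0, -1.0, 0.0])
        d = np.tile(t, (n, 1))
        corrupt = rng.choice(n, size=outliers, replace=False)
        d[corrupt] += rng.normal(scale=12.0, size=(outliers, 3))
        return _field_at(pts, d), corrupt

    def test_zero_rejection_fraction_keeps_all_blocks(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(2)
        field, _ = self._consistent_field(mesh, rng)
        cfg = RegistrationConfig(F_r=1e-9, N_rej=1)
        _, out, trace = register_pbnrr(mesh, field, cfg)
        assert out.active.all()

    def test_exact_rejection_arithmetic(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(3)
        field, _ = self._consistent_field(mesh, rng, n=100)
        cfg = RegistrationConfig(F_r=0.25, N_rej=10)
        _, out, trace = register_pbnrr(mesh, field, cfg)
        assert out.active.sum() == 75

    def test_planted_outliers_are_deactivated(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(4)
        field, corrupt = self._consistent_field(mesh, rng, n=120, outliers=12)
        cfg = RegistrationConfig(F_r=0.25, N_rej=10)
        _, out, _ = register_pbnrr(mesh, field, cfg)
        caught = (~out.active[corrupt]).mean()
        assert caught >= 0.9

    def test_objective_non_increasing_across_rejection_steps(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(5)
        field, _ = self._consistent_field(mesh, rng, n=120, outliers=12)
        cfg = RegistrationConfig(F_r=0.25, N_rej=10)
        _, _, trace = register_pbnrr(mesh, field, cfg)
        objs = [s["objective"] for s in trace["steps"]] + [trace["final"]["objective"]]
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_stiffer_tumor_deforms_less_than_parenchyma(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(6)
        # radial squeeze applied at the outer boundary of the sphere
        pts = mesh.vertices[np.unique(mesh.boundary_faces())][::3]
        center = np.array([24.0, 24.0, 24.0])
        d = -0.15 * (pts - center)
        field = _field_at(pts, d)
        cfg = RegistrationConfig(F_r=1e-9, N_rej=1, lambda_reg=1.0)
        U, _, _ = register_pbnrr(mesh, field, cfg)
        disp = np.linalg.norm(U, axis=1)
        tumor_vertices = np.unique(mesh.tets[mesh.tissue == TUMOR])
        par_vertices = np.setdiff1d(np.unique(mesh.tets), tumor_vertices)
        assert disp[tumor_vertices].mean() <= disp[par_vertices].mean()


class TestDenseFieldAndWarp:
    def test_linear_nodal_field_reproduced_on_the_grid(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        rng = np.random.default_rng(7)
        A = rng.normal(scale=0.05, size=(3, 3))
        b = rng.normal(size=3)
        U = mesh.vertices @ A.T + b
        grid = ImageVolume(np.zeros(sphere_labels.shape), sphere_labels.spacing)
        u, inside = dense_field(mesh, U, grid)
        pts = grid.grid_points()
        expected = pts @ A.T + b
        assert np.allclose(u[inside], expected[inside], atol=1e-10)
        assert np.abs(u[~inside]).max() == 0.0

    def test_constant_nodal_field_fills_inside_mask(self, sphere_labels):
        mesh = build_mesh(sphere_labels, 5.0)
        t = np.array([1.0, 2.0, 3.0])
        grid = ImageVolume(np.zeros(sphere_labels.shape), sphere_labels.spacing)
        u, inside = dense_field(mesh, np.tile(t, (mesh.n_vertices, 1)), grid)
        assert np.allclose(u[inside], t, atol=1e-12)

    def test_zero_field_warp_is_bit_exact(self):
        rng = np.random.default_rng(8)
        img = ImageVolume(rng.normal(size=(12, 12, 12)))
        out = warp_image(img, np.zeros((12, 12, 12, 3)))
        assert np.array_equal(out.data, img.data)

    def test_constant_integer_translation_matches_array_shift(self):
        rng = np.random.default_rng(9)
        img = ImageVolume(rng.normal(size=(16, 16, 16)), (2.0, 2.0, 2.0))
        u = np.zeros((16, 16, 16, 3))
        u[..., 0] = 4.0  # +2 voxels: material moves +x, so output is shifted
        out = warp_image(img, u)
        assert np.allclose(out.data[2:, :, :], img.data[:-2, :, :], atol=1e-12)

    def test_field_inversion_converges_for_smooth_fields(self):
        shape = (20, 20, 20)
        grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                        axis=-1).astype(float)
        r2 = ((grid - 10.0) ** 2).sum(axis=-1)
        u = np.zeros(shape + (3,))
        u[..., 0] = 1.5 * np.exp(-r2 / 40.0)
        v, bad = invert_field(u, (1.0, 1.0, 1.0))
        assert bad == 0
        # composition x -> (x - v) -> + u should return to x
        from apbnrr.fem import _sample_field
        back = _sample_field(u, grid - v)
        assert np.abs(back - v).max() < 0.15
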