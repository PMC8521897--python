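"""Linear-elastic finite-element registration core.

The sparse block-matching displacements D at block centers drive a P1
tetrahedral linear-elastic brain model: the nodal displacement U solves

    U = argmin  (H U - D)^T S (H U - D)  +  lambda * U^T K U

via the normal equations ``(lambda K + H^T S H) U = H^T S D``, where H
interpolates nodal values at block centers (barycentric P1), S is a
per-block confidence (the NCC score), and K the assembled stiffness.
Outliers are rejected by iterative trimming: over ``N_rej`` steps the
fraction ``F_r`` of blocks with the largest residual |H_b U - D_b| is
deactivated and the system re-solved.

K is assembled in (Pa, mm); the solver normalizes it by the parenchyma
modulus and the mean edge length, so ``lambda_reg`` is dimensionless and
only the tissue stiffness ratio matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu

from .core import PARENCHYMA, TUMOR, ImageVolume, RegistrationConfig
from .blockmatch import SparseDisplacementField
from .mesher import TetLocator, TetMesh


@dataclass
class MaterialTable:
    """Isotropic linear-elastic parameters per tissue label."""

    materials: dict  # label -> (E Pa, nu)

    def __post_init__(self) -> None:
        for label, (E, nu) in self.materials.items():
            if E <= 0:
                raise ValueError(f"Young's modulus must be > 0 for label {label}")
            if not 0 <= nu < 0.5:
                raise ValueError(f"Poisson ratio must be in [0, 0.5) for label {label}")

    @classmethod
    def from_config(cls, config: RegistrationConfig) -> "MaterialTable":
        return cls({PARENCHYMA: (config.E_b, config.V_b), TUMOR: (config.E_t, config.V_t)})

    def __getitem__(self, label: int):
        return self.materials[label]


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt notation."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def assemble_stiffness(mesh: TetMesh, materials: MaterialTable) -> sparse.csr_matrix:
    """Assemble the 3n x 3n P1 tetrahedral linear-elasticity stiffness matrix.

    Symmetric, positive semidefinite, with rigid translations in its null
    space; linear in each tissue's Young's modulus.
    """
    coords = mesh.tet_coords()
    vol = mesh.volumes()
    if np.any(np.abs(vol) < 1e-12):
        bad = np.where(np.abs(vol) < 1e-12)[0]
        raise ValueError(f"degenerate (zero-volume) tets at indices {bad.tolist()}")
    m = mesh.n_tets
    # Barycentric gradients: grad(l_i) rows of inverse of [1 x y z] matrix.
    ones = np.ones((m, 4, 1))
    A = np.concatenate([ones, coords], axis=2)  # (m, 4, 4)
    Ainv = np.linalg.inv(A)
    grads = Ainv[:, 1:, :].transpose(0, 2, 1)  # (m, 4 nodes, 3 derivs)

    # B matrix (6 x 12) per tet, Voigt [xx, yy, zz, xy, yz, xz].
    B = np.zeros((m, 6, 12))
    for node in range(4):
        gx, gy, gz = grads[:, node, 0], grads[:, node, 1], grads[:, node, 2]
        c = 3 * node
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx

    labels = np.unique(mesh.tissue)
    Ke = np.zeros((m, 12, 12))
    for label in labels:
        sel = mesh.tissue == label
        D = _elasticity_matrix(*materials[int(label)])
        Ke[sel] = np.einsum("mji,jk,mkl,m->mil", B[sel], D, B[sel], np.abs(vol[sel]))

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_vertices,) * 2)
    K = K.tocsr()
    return 0.5 * (K + K.T)  # enforce exact symmetry against rounding


def assemble_coupling(mesh: TetMesh, field: SparseDisplacementField,
                      locator: TetLocator | None = None):
    """Interpolation matrix H, confidence S and data vector D for usable blocks.

    H maps nodal displacements to block-center displacements by barycentric
    (P1) interpolation in the containing tet; S is block-diagonal with
    ``score * I3`` per block. Blocks outside the mesh, inactive, or flagged
    zero-correspondence are excluded; their indices are returned.
    """
    if locator is None:
        locator = TetLocator(mesh)
    usable = np.where(field.usable())[0]
    if len(usable) == 0:
        raise ValueError("no usable blocks (all inactive or zero-correspondence)")
    tet_idx, bary = locator.locate(field.centers_mm[usable])
    inside = tet_idx >= 0
    used = usable[inside]
    excluded = np.setdiff1d(np.arange(len(field)), used)
    if len(used) == 0:
        raise ValueError("no usable blocks inside the mesh")
    tet_idx = tet_idx[inside]
    bary = bary[inside]

    nb = len(used)
    n_dof = 3 * mesh.n_vertices
    rows = np.repeat(np.arange(3 * nb), 4)
    verts = mesh.tets[tet_idx]  # (nb, 4)
    cols = (3 * verts[:, None, :] + np.arange(3)[None, :, None]).reshape(nb * 3, 4).ravel()
    vals = np.repeat(bary[:, None, :], 3, axis=1).reshape(nb * 3, 4).ravel()
    H = sparse.coo_matrix((vals, (rows, cols)), shape=(3 * nb, n_dof)).tocsr()

    s = np.maximum(field.scores[used], 1e-6)  # guard non-positive confidences
    S = sparse.diags(np.repeat(s, 3))
    D = field.displacements_mm[used].ravel()
    return H, S, D, used, excluded


def solve_approximation(K: sparse.spmatrix, H: sparse.spmatrix, S: sparse.spmatrix,
                        D: np.ndarray, lambda_reg: float) -> np.ndarray:
    """Solve ``(lambda K + H^T S H) U = H^T S D``; returns U as (n, 3) mm."""
    A = (lambda_reg * K + H.T @ S @ H).tocsc()
    b = H.T @ (S @ D)
    try:
        lu = splu(A)
    except RuntimeError as exc:
        raise ValueError(
            "singular registration system (blocks collinear or too few); "
            f"solver said: {exc}"
        ) from exc
    U = lu.solve(b)
    if not np.all(np.isfinite(U)):
        raise ValueError("singular registration system: non-finite solution")
    return U.reshape(-1, 3)


def normalized_stiffness(K: sparse.spmatrix, mesh: TetMesh, E_ref: float) -> sparse.spmatrix:
    """Dimensionless stiffness: K / (E_ref * mean edge length)."""
    edges = mesh.edges()
    h_mean = float(np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]],
                                  axis=1).mean())
    return K / (E_ref * h_mean)


def register_pbnrr(mesh: TetMesh, field: SparseDisplacementField,
                   config: RegistrationConfig, locator: TetLocator | None = None):
    """PBNRR solve with iterative outlier rejection.

    Over ``N_rej`` steps, solves the approximation system and deactivates
    the ``F_r / N_rej`` fraction of currently-active blocks with the
    largest per-block error |H_b U - D_b| (floor per step, remainder in the
    last step; ties deactivate the larger block index first), so that
    ``floor(F_r * N0)`` of the initially active blocks end up inactive.

    Returns (U (n,3) mm, updated field, trace dict).
    """
    if locator is None:
        locator = TetLocator(mesh)
    K = assemble_stiffness(mesh, MaterialTable.from_config(config))
    K_hat = normalized_stiffness(K, mesh, config.E_b)

    field = SparseDisplacementField(
        field.centers_vox, field.centers_mm, field.displacements_mm,
        field.scores, field.zero_correspondence, field.active.copy(),
    )
    H, S, D, used, _ = assemble_coupling(mesh, field, locator)
    n0 = len(used)
    if n0 < 4:
        raise ValueError(f"only {n0} usable blocks; at least 4 required")
    total_remove = int(np.floor(config.F_r * n0))
    if n0 - total_remove < 4:
        raise ValueError("trimming would leave fewer than 4 active blocks")
    per_step = total_remove // config.N_rej

    trace = {"steps": []}
    U = None
    for step in range(config.N_rej):
        H, S, D, used, _ = assemble_coupling(mesh, field, locator)
        U = solve_approximation(K_hat, H, S, D, config.lambda_reg)
        resid = (H @ U.ravel() - D).reshape(-1, 3)
        err = np.linalg.norm(resid, axis=1)
        k = per_step if step < config.N_rej - 1 else total_remove - per_step * (config.N_rej - 1)
        if k > 0:
            # Largest error first; ties deactivate the larger block index first.
            order = np.lexsort((-used, -err))
            field.active[used[order[:k]]] = False
        s = np.maximum(field.scores[used], 1e-6)
        data_term = float(np.sum(s * err**2))
        reg_term = float(config.lambda_reg * U.ravel() @ (K_hat @ U.ravel()))
        trace["steps"].append({
            "step": step,
            "n_active": int(field.active.sum()),
            "n_used": len(used),
            "rms_error_mm": float(np.sqrt((err**2).mean())),
            "objective": data_term + reg_term,
        })
    # Final solve on the trimmed set.
    H, S, D, used, _ = assemble_coupling(mesh, field, locator)
    U = solve_approximation(K_hat, H, S, D, config.lambda_reg)
    resid = (H @ U.ravel() - D).reshape(-1, 3)
    err = np.linalg.norm(resid, axis=1)
    s = np.maximum(field.scores[used], 1e-6)
    trace["final"] = {
        "n_active": int(field.active.sum()),
        "n_used": len(used),
        "rms_error_mm": float(np.sqrt((err**2).mean())),
        "objective": float(np.sum(s * err**2))
        + float(config.lambda_reg * U.ravel() @ (K_hat @ U.ravel())),
        "max_U_mm": float(np.linalg.norm(U, axis=1).max()),
    }
    return U, field, trace


def dense_field(mesh: TetMesh, U: np.ndarray, grid) -> tuple[np.ndarray, np.ndarray]:
    """P1-interpolate nodal displacements at voxel centers inside the mesh.

    Returns (u, inside) where ``u`` has shape grid.shape + (3,) in mm and is
    zero outside the mesh, and ``inside`` is the defined-inside-mesh mask.
    """
    U = np.asarray(U, dtype=float).reshape(-1, 3)
    shape = np.asarray(grid.shape)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    u = np.zeros(tuple(shape) + (3,))
    inside = np.zeros(tuple(shape), dtype=bool)
    coords = mesh.tet_coords()
    v0 = coords[:, 0]
    # Rows are edge vectors, so lambda = (p - v0) @ inv per tet.
    edge = np.stack([coords[:, 1] - v0, coords[:, 2] - v0, coords[:, 3] - v0], axis=1)
    inv = np.linalg.inv(edge)
    for t in range(len(coords)):
        lo = np.maximum(np.ceil((coords[t].min(axis=0) - origin) / spacing - 1e-9), 0).astype(int)
        hi = np.minimum(np.floor((coords[t].max(axis=0) - origin) / spacing + 1e-9),
                        shape - 1).astype(int)
        if np.any(hi < lo):
            continue
        ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij")
        vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        pts = vox * spacing + origin
        lam = (pts - v0[t]) @ inv[t]
        l0 = 1.0 - lam.sum(axis=1)
        good = (lam.min(axis=1) >= -1e-9) & (l0 >= -1e-9)
        if not good.any():
            continue
        sel = vox[good]
        bary = np.concatenate([l0[good, None], lam[good]], axis=1)  # (p, 4)
        vals = bary @ U[mesh.tets[t]]  # (p, 3)
        u[sel[:, 0], sel[:, 1], sel[:, 2]] = vals
        inside[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return u, inside


def extrapolate_field(u: np.ndarray, inside: np.ndarray,
                      target_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor extrapolation of a dense field onto extra voxels.

    Voxels of ``target_mask`` outside the defined region take the value of
    the nearest defined voxel (e.g. to cover an excised resection cavity
    with the surrounding rim displacement). Returns (field, defined mask).
    """
    inside = np.asarray(inside, dtype=bool)
    fill = np.asarray(target_mask, dtype=bool) & ~inside
    if not fill.any() or not inside.any():
        return u, inside
    _, idx = ndimage.distance_transform_edt(~inside, return_indices=True)
    out = u.copy()
    out[fill] = u[idx[0][fill], idx[1][fill], idx[2][fill]]
    return out, inside | fill


def _sample_field(u: np.ndarray, vox: np.ndarray, mode: str = "constant") -> np.ndarray:
    """Trilinear sample of a (ni,nj,nk,3) field at fractional voxel coords."""
    out = np.empty(vox.shape[:-1] + (3,))
    coords = [vox[..., a] for a in range(3)]
    for a in range(3):
        out[..., a] = ndimage.map_coordinates(u[..., a], coords, order=1,
                                              mode=mode, cval=0.0)
    return out


def invert_field(u: np.ndarray, spacing, tol_voxel: float = 0.1,
                 max_iter: int = 20) -> tuple[np.ndarray, int]:
    """Fixed-point inversion of a forward displacement field.

    Given the forward field u (material points p map to p + u(p)), returns
    the pull-back field v with v(x) = u(x - v(x)) and the count of voxels
    that did not converge to ``tol_voxel`` within ``max_iter`` iterations.
    """
    spacing = np.asarray(spacing, dtype=float)
    shape = u.shape[:-1]
    grid_vox = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    v = np.zeros_like(u)
    tol_mm = tol_voxel * spacing.min()
    delta = np.full(shape, np.inf)
    for _ in range(max_iter):
        sample_vox = grid_vox - v / spacing
        # nearest-extension avoids flip-flopping against zero padding at the
        # grid boundary
        v_new = _sample_field(u, sample_vox, mode="nearest")
        delta = np.linalg.norm(v_new - v, axis=-1)
        v = v_new
        if delta.max() < tol_mm:
            break
    return v, int((delta >= tol_mm).sum())


def warp_image(moving: ImageVolume, u: np.ndarray, fill: float = 0.0,
               order: int = 1) -> ImageVolume:
    """Warp the (preoperative) moving image through the forward field u.

    ``u`` is the displacement of preoperative material points toward
    intraoperative space, given on the output grid. The output is
    ``out(x) = moving(x - v(x))`` with v the fixed-point inverse of u and
    trilinear sampling (``order=0`` for label images). Out-of-domain
    samples take ``fill``.
    """
    v, _ = invert_field(np.asarray(u, dtype=float), moving.spacing)
    shape = moving.shape
    grid_vox = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    sample_vox = grid_vox - v / np.asarray(moving.spacing)
    data = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float),
        [sample_vox[..., a] for a in range(3)],
        order=order, mode="constant", cval=fill,
    )
    return moving.with_data(data)
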