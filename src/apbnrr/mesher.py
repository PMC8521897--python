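"""Multi-tissue tetrahedral meshing of a label map.

The mesher tessellates a body-centered-cubic (BCC) lattice at pitch
``delta`` (in voxels of the label grid), keeps tetrahedra overlapping the
labeled region, snaps outside boundary vertices onto the segmentation
surface, and assigns each element the majority tissue label it overlaps.
BCC lattices give deterministic, guaranteed-quality tetrahedra, and a
smaller ``delta`` produces a larger mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BACKGROUND, PARENCHYMA, TUMOR, LabelMap

_DEGENERATE_VOLUME = 1e-9  # mm^3


@dataclass
class TetMesh:
    """Tetrahedral mesh: vertices in mm, 4-index cells, per-cell tissue label."""

    vertices: np.ndarray  # (n, 3) float, mm
    tets: np.ndarray      # (m, 4) int
    tissue: np.ndarray    # (m,) int in {1 parenchyma, 2 tumor}

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.tissue = np.asarray(self.tissue, dtype=np.int64).reshape(-1)
        if len(self.tissue) != len(self.tets):
            raise ValueError("tissue must be defined for every tet")
        if len(self.tets) and (self.tets.min() < 0 or self.tets.max() >= len(self.vertices)):
            raise ValueError("tet indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_coords(self) -> np.ndarray:
        """Vertex coordinates per tet, shape (m, 4, 3)."""
        return self.vertices[self.tets]

    def volumes(self) -> np.ndarray:
        """Signed tet volumes (mm^3); positive under the orientation convention."""
        c = self.tet_coords()
        e = c[:, 1:] - c[:, :1]
        return np.einsum("mi,mi->m", np.cross(e[:, 0], e[:, 1]), e[:, 2]) / 6.0

    def centroids(self) -> np.ndarray:
        return self.tet_coords().mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique sorted vertex-index pairs, shape (n_edges, 2)."""
        pairs = self.tets[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2)
        return np.unique(np.sort(pairs, axis=1), axis=0)

    def boundary_faces(self) -> np.ndarray:
        """Faces referenced by exactly one tet, shape (n_faces, 3)."""
        faces = self.tets[:, [0, 1, 2, 0, 1, 3, 0, 2, 3, 1, 2, 3]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def oriented(self) -> "TetMesh":
        """Flip negatively-oriented tets so all signed volumes are positive."""
        vol = self.volumes()
        tets = self.tets.copy()
        flip = vol < 0
        tets[flip] = tets[flip][:, [0, 2, 1, 3]]
        return TetMesh(self.vertices, tets, self.tissue)

    def compacted(self) -> "TetMesh":
        """Drop unused vertices, remapping indices."""
        used = np.unique(self.tets)
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TetMesh(self.vertices[used], remap[self.tets], self.tissue)


@dataclass
class MeshQualityReport:
    n_vertices: int
    n_tets: int
    min_dihedral_deg: float
    mean_dihedral_deg: float
    fidelity_mean_mm: float
    fidelity_p95_mm: float
    degenerate_tets: list

    def as_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_tets": self.n_tets,
            "min_dihedral_deg": self.min_dihedral_deg,
            "mean_dihedral_deg": self.mean_dihedral_deg,
            "fidelity_mean_mm": self.fidelity_mean_mm,
            "fidelity_p95_mm": self.fidelity_p95_mm,
            "degenerate_tets": list(self.degenerate_tets),
        }


# Opposite-vertex pairs defining the six dihedral edges of a tet.
_EDGE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_FACES = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]  # face i excludes vertex i


def dihedral_angles(coords: np.ndarray) -> np.ndarray:
    """Six dihedral angles (degrees) per tet; coords shape (m, 4, 3)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 4, 3)
    # Inward normal of face i (opposite vertex i).
    normals = np.empty((len(coords), 4, 3))
    for i, (a, b, c) in enumerate(_FACES):
        n = np.cross(coords[:, b] - coords[:, a], coords[:, c] - coords[:, a])
        # orient toward the excluded vertex
        to_v = coords[:, i] - coords[:, a]
        sign = np.sign(np.einsum("mi,mi->m", n, to_v))
        sign[sign == 0] = 1.0
        normals[:, i] = n * sign[:, None]
    norms = np.linalg.norm(normals, axis=2)
    norms[norms == 0] = 1.0
    normals = normals / norms[:, :, None]
    angles = np.empty((len(coords), 6))
    for e, (i, j) in enumerate(_EDGE_PAIRS):
        # The dihedral along edge (i, j) is between the two faces containing it,
        # i.e. the faces opposite the OTHER two vertices.
        k, l = [v for v in range(4) if v not in (i, j)]
        cosang = -np.einsum("mi,mi->m", normals[:, k], normals[:, l])
        angles[:, e] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles


def _bcc_lattice(labels: LabelMap, delta: float):
    """BCC vertices (mm) and tets over the bounding box of the labeled region."""
    mask = labels.brain_mask()
    if not mask.any():
        raise ValueError("label map contains no labeled (brain) voxels")
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(labels.origin)
    pitch = delta * spacing  # mm per lattice cell, per axis

    idx = np.argwhere(mask)
    lo_mm = origin + idx.min(axis=0) * spacing
    hi_mm = origin + idx.max(axis=0) * spacing
    lo_cell = np.floor((lo_mm - origin) / pitch).astype(int) - 1
    hi_cell = np.ceil((hi_mm - origin) / pitch).astype(int) + 1
    ncell = hi_cell - lo_cell  # number of cells per axis
    if np.any(ncell < 1):
        raise ValueError(f"delta={delta} too large: no lattice cell fits the labeled region")
    npts = ncell + 1

    # Primal lattice points, then cell centers.
    pi, pj, pk = [np.arange(lo_cell[a], hi_cell[a] + 1) for a in range(3)]
    primal = np.stack(np.meshgrid(pi, pj, pk, indexing="ij"), axis=-1).reshape(-1, 3)
    ci, cj, ck = [np.arange(lo_cell[a], hi_cell[a]) + 0.5 for a in range(3)]
    centers = np.stack(np.meshgrid(ci, cj, ck, indexing="ij"), axis=-1).reshape(-1, 3)
    vertices = np.concatenate([primal, centers], axis=0) * pitch + origin

    def primal_id(c):  # c integer (n, 3)
        r = c - lo_cell
        return (r[:, 0] * npts[1] + r[:, 1]) * npts[2] + r[:, 2]

    def center_id(c):  # c integer cell index (n, 3)
        r = c - lo_cell
        return len(primal) + (r[:, 0] * ncell[1] + r[:, 1]) * ncell[2] + r[:, 2]

    # Tets: for each pair of face-adjacent cells, 4 tets joining the two cell
    # centers with consecutive corners of the shared face.
    tets = []
    for axis in range(3):
        shape = ncell.copy()
        shape[axis] -= 1
        if shape[axis] < 1:
            continue
        cells = np.stack(
            np.meshgrid(*[np.arange(shape[a]) for a in range(3)], indexing="ij"), axis=-1
        ).reshape(-1, 3) + lo_cell
        c1 = center_id(cells)
        nxt = cells.copy()
        nxt[:, axis] += 1
        c2 = center_id(nxt)
        # Shared face corners: cell corner at offset e_axis, spanned by the
        # other two axes, ordered cyclically.
        a1, a2 = [a for a in range(3) if a != axis]
        base = cells.copy()
        base[:, axis] += 1
        cyc = [(0, 0), (1, 0), (1, 1), (0, 1)]
        corner_ids = []
        for o1, o2 in cyc:
            c = base.copy()
            c[:, a1] += o1
            c[:, a2] += o2
            corner_ids.append(primal_id(c))
        for m in range(4):
            q0, q1 = corner_ids[m], corner_ids[(m + 1) % 4]
            tets.append(np.stack([c1, c2, q0, q1], axis=1))
    return vertices, np.concatenate(tets, axis=0)


def _sample_labels(labels: LabelMap, points_mm: np.ndarray) -> np.ndarray:
    """Nearest-voxel label lookup at physical points; outside grid -> background."""
    vox = np.rint(labels.voxel(points_mm)).astype(int)
    shape = np.asarray(labels.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=-1)
    out = np.zeros(len(points_mm), dtype=int)
    v = vox[inside]
    out[inside] = labels.labels[v[:, 0], v[:, 1], v[:, 2]]
    return out


def _tet_sample_points(coords: np.ndarray) -> np.ndarray:
    """Label-sampling points per tet: 4 vertices, centroid, 4 mid vertex-centroid."""
    cent = coords.mean(axis=1, keepdims=True)
    mids = 0.5 * (coords + cent)
    return np.concatenate([coords, cent, mids], axis=1)  # (m, 9, 3)


def _majority_tissue(labels: LabelMap, coords: np.ndarray) -> np.ndarray:
    """Majority tissue label per tet from sampled points; ties -> parenchyma."""
    samples = _tet_sample_points(coords)
    m, s, _ = samples.shape
    lab = _sample_labels(labels, samples.reshape(-1, 3)).reshape(m, s)
    n_tum = (lab == TUMOR).sum(axis=1)
    n_par = (lab == PARENCHYMA).sum(axis=1)
    return np.where(n_tum > n_par, TUMOR, PARENCHYMA)


def build_mesh(labels: LabelMap, delta: float = 5.0) -> TetMesh:
    """Tessellate the labeled region with BCC tetrahedra at pitch ``delta`` voxels.

    Keeps tets with at least one vertex or the centroid inside the labeled
    region, snaps boundary vertices lying outside onto the segmentation
    surface (one projection pass, reverting moves that would invert
    elements), and assigns the majority tissue label to each element.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    vertices, tets = _bcc_lattice(labels, delta)
    spacing = np.asarray(labels.spacing)
    pitch_mm = float(delta * spacing.min())

    coords = vertices[tets]
    cent_inside = _sample_labels(labels, coords.mean(axis=1)) > BACKGROUND
    tets = tets[cent_inside]
    if len(tets) == 0:
        raise ValueError("no tetrahedra overlap the labeled region")

    mesh = TetMesh(vertices, tets, np.ones(len(tets), dtype=int)).compacted().oriented()
    vertices = mesh.vertices.copy()
    tets = mesh.tets

    # Signed distance to the segmentation surface (positive outside), in mm.
    # The surface sits at the interpolated zero crossing, half a voxel past
    # the outermost labeled voxel centers.
    mask = labels.brain_mask()
    d_out = ndimage.distance_transform_edt(~mask, sampling=labels.spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=labels.spacing)
    sdist = d_out - d_in
    grad = np.stack(np.gradient(sdist, *labels.spacing), axis=-1)

    def _sample(vol, pts):
        pts = np.atleast_2d(pts)
        vox = labels.voxel(pts)
        vox = np.clip(vox.T, 0, (np.asarray(labels.shape) - 1)[:, None])
        if vol.ndim == 3:
            return ndimage.map_coordinates(vol, vox, order=1, mode="nearest")
        return np.stack(
            [ndimage.map_coordinates(vol[..., a], vox, order=1, mode="nearest")
             for a in range(3)], axis=-1)

    # Projection pass: snap boundary vertices near the surface onto it.
    bverts = np.unique(mesh.boundary_faces())
    p = vertices[bverts]
    dist0 = _sample(sdist, p)
    near = np.abs(dist0) <= 0.9 * pitch_mm
    target = p.copy()
    for _ in range(4):  # fixed-point projection on the interpolated distance
        s = _sample(sdist, target)
        g = _sample(grad, target)
        gn = np.linalg.norm(g, axis=1)
        gn[gn == 0] = 1.0
        step = np.clip(s, -0.8 * pitch_mm, 0.8 * pitch_mm)
        target = target - (g / gn[:, None]) * step[:, None]
    # Apply moves one vertex at a time, halving the step (then reverting)
    # whenever an incident element would degenerate or invert.
    incident: dict[int, list[int]] = {}
    for t, tet in enumerate(tets):
        for v in tet:
            incident.setdefault(int(v), []).append(t)

    def _incident_ok(v: int) -> bool:
        local = TetMesh(vertices, tets[incident[int(v)]],
                        np.ones(len(incident[int(v)]), dtype=int))
        return bool((local.volumes() > _DEGENERATE_VOLUME * 100).all())

    for b, v in enumerate(bverts):
        if not near[b]:
            continue
        old = vertices[v].copy()
        full = target[b] - old
        for frac in (1.0, 0.5, 0.25):
            vertices[v] = old + frac * full
            if _incident_ok(int(v)):
                break
        else:
            vertices[v] = old

    mesh = TetMesh(vertices, tets, np.ones(len(tets), dtype=int)).oriented()
    vol = mesh.volumes()
    degenerate = np.abs(vol) < _DEGENERATE_VOLUME
    if degenerate.any():
        warnings.warn(f"dropping {int(degenerate.sum())} degenerate tetrahedra")
        mesh = TetMesh(mesh.vertices, mesh.tets[~degenerate], mesh.tissue[~degenerate]).compacted()

    tissue = _majority_tissue(labels, mesh.tet_coords())
    return TetMesh(mesh.vertices, mesh.tets, tissue)


def quality_report(mesh: TetMesh, labels: LabelMap | None = None) -> MeshQualityReport:
    """Per-mesh quality (dihedral angles) and fidelity (two-sided surface distance)."""
    vol = mesh.volumes()
    degenerate = np.where(np.abs(vol) < _DEGENERATE_VOLUME)[0]
    ok = np.abs(vol) >= _DEGENERATE_VOLUME
    ang = dihedral_angles(mesh.tet_coords()[ok])
    fid_mean = fid_p95 = float("nan")
    if labels is not None:
        mask = labels.brain_mask()
        eroded = ndimage.binary_erosion(mask)
        surf_vox = np.argwhere(mask & ~eroded)
        surf_pts = labels.physical(surf_vox)
        faces = mesh.boundary_faces()
        fc = mesh.vertices[faces]
        mesh_pts = np.concatenate([fc.mean(axis=1), fc.reshape(-1, 3)], axis=0)
        if len(surf_pts) and len(mesh_pts):
            d1, _ = cKDTree(surf_pts).query(mesh_pts)
            d2, _ = cKDTree(mesh_pts).query(surf_pts)
            d = np.concatenate([d1, d2])
            fid_mean = float(d.mean())
            fid_p95 = float(np.percentile(d, 95))
    return MeshQualityReport(
        n_vertices=mesh.n_vertices,
        n_tets=mesh.n_tets,
        min_dihedral_deg=float(ang.min()) if len(ang) else float("nan"),
        mean_dihedral_deg=float(ang.mean()) if len(ang) else float("nan"),
        fidelity_mean_mm=fid_mean,
        fidelity_p95_mm=fid_p95,
        degenerate_tets=degenerate.tolist(),
    )


def remove_elements(mesh: TetMesh, tet_ids) -> TetMesh:
    """Remove the listed tets, dropping orphaned vertices with index remapping."""
    tet_ids = np.asarray(tet_ids, dtype=int)
    if len(tet_ids) and (tet_ids.min() < 0 or tet_ids.max() >= mesh.n_tets):
        raise ValueError("tet ids out of range")
    keep = np.ones(mesh.n_tets, dtype=bool)
    keep[tet_ids] = False
    if not keep.any():
        raise ValueError("removal would leave an empty mesh")
    return TetMesh(mesh.vertices, mesh.tets[keep], mesh.tissue[keep]).compacted()


def retessellate(mesh: TetMesh, labels_minus_cavity: LabelMap, delta: float) -> TetMesh:
    """Fresh build on the cavity-updated label map (quality over naive removal)."""
    return build_mesh(labels_minus_cavity, delta)


def coverage_stats(mesh: TetMesh, labels: LabelMap) -> dict:
    """Volume agreement between the mesh and the labeled region.

    ``coverage`` is the fraction of labeled voxel centers inside the mesh;
    ``spillover`` the fraction of inside-mesh voxel centers that are unlabeled;
    ``volume_ratio`` total tet volume over labeled voxel volume.
    """
    inside = rasterize_inside_mask(mesh, labels)
    mask = labels.brain_mask()
    coverage = float((inside & mask).sum() / max(mask.sum(), 1))
    spillover = float((inside & ~mask).sum() / max(inside.sum(), 1))
    volume_ratio = float(np.abs(mesh.volumes()).sum() / (mask.sum() * labels.voxel_volume()))
    return {"coverage": coverage, "spillover": spillover, "volume_ratio": volume_ratio}


def rasterize_inside_mask(mesh: TetMesh, grid) -> np.ndarray:
    """Boolean mask of voxel centers inside the mesh, on the geometry of ``grid``."""
    shape = np.asarray(grid.shape)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    inside = np.zeros(tuple(shape), dtype=bool)
    coords = mesh.tet_coords()
    v0 = coords[:, 0]
    # Rows are edge vectors, so lambda = (p - v0) @ inv per tet.
    edge = np.stack([coords[:, 1] - v0, coords[:, 2] - v0, coords[:, 3] - v0], axis=1)
    inv = np.linalg.inv(edge)  # (m, 3, 3)
    tol = 1e-9
    for t in range(len(coords)):
        lo = np.maximum(np.ceil((coords[t].min(axis=0) - origin) / spacing - tol), 0).astype(int)
        hi = np.minimum(np.floor((coords[t].max(axis=0) - origin) / spacing + tol), shape - 1).astype(int)
        if np.any(hi < lo):
            continue
        ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing + origin
        lam = (pts - v0[t]) @ inv[t]
        good = (lam.min(axis=1) >= -1e-9) & (lam.sum(axis=1) <= 1 + 1e-9)
        if good.any():
            sel = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)[good]
            inside[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return inside


class TetLocator:
    """Point-in-mesh queries via a uniform bucket grid over tet bounding boxes."""

    def __init__(self, mesh: TetMesh, bucket_size: float | None = None):
        self.mesh = mesh
        coords = mesh.tet_coords()
        self._v0 = coords[:, 0]
        # Rows are edge vectors, so lambda = (p - v0) @ inv per tet.
        edge = np.stack([coords[:, 1] - coords[:, 0],
                         coords[:, 2] - coords[:, 0],
                         coords[:, 3] - coords[:, 0]], axis=1)
        self._inv = np.linalg.inv(edge)
        self._lo = coords.min(axis=(0, 1))
        hi = coords.max(axis=(0, 1))
        if bucket_size is None:
            mean_edge = float(np.linalg.norm(coords[:, 1] - coords[:, 0], axis=1).mean())
            bucket_size = max(mean_edge, 1e-6)
        self._h = bucket_size
        self._nb = np.maximum(np.ceil((hi - self._lo) / self._h).astype(int), 1)
        self._buckets: dict[tuple, list] = {}
        tlo = np.floor((coords.min(axis=1) - self._lo) / self._h).astype(int)
        thi = np.floor((coords.max(axis=1) - self._lo) / self._h).astype(int)
        for t in range(len(coords)):
            for i in range(tlo[t, 0], thi[t, 0] + 1):
                for j in range(tlo[t, 1], thi[t, 1] + 1):
                    for k in range(tlo[t, 2], thi[t, 2] + 1):
                        self._buckets.setdefault((i, j, k), []).append(t)

    def locate(self, points: np.ndarray, tol: float = 1e-9):
        """Containing tet index per point (-1 if outside) and barycentric coords."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        tet_idx = -np.ones(len(pts), dtype=np.int64)
        bary = np.zeros((len(pts), 4))
        cell = np.floor((pts - self._lo) / self._h).astype(int)
        for p in range(len(pts)):
            cand = self._buckets.get(tuple(cell[p]))
            if not cand:
                continue
            cand = np.asarray(cand)
            lam = np.einsum("i,mij->mj", pts[p], self._inv[cand]) - np.einsum(
                "mi,mij->mj", self._v0[cand], self._inv[cand]
            )
            l0 = 1.0 - lam.sum(axis=1)
            ok = (lam.min(axis=1) >= -tol) & (l0 >= -tol)
            hits = np.where(ok)[0]
            if len(hits):
                t = cand[hits[0]]
                tet_idx[p] = t
                bary[p, 1:] = lam[hits[0]]
                bary[p, 0] = l0[hits[0]]
        return tet_idx, bary
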