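"""File I/O: images (NIfTI-1, MetaImage), landmarks (CSV), configs (YAML),
meshes and metric fields (VTK legacy unstructured grid), dense fields (NIfTI).

Physical convention on disk matches :mod:`apbnrr.core`: axis-aligned grids,
``physical = origin + index * spacing``. NIfTI affines are written as
``diag(spacing)`` with the origin in the translation column; oblique
direction matrices are rejected on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .core import ImageVolume, LabelMap, LandmarkSet, RegistrationConfig, RigidTransform

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path: str | Path) -> ImageVolume:
    """Read a 3D scalar volume from NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        spacing = np.sqrt((rot**2).sum(axis=0))
        if np.any(spacing <= 0):
            raise ValueError(f"non-positive spacing in {path}")
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError(f"oblique direction matrix in {path} is unsupported")
        diag = np.diag(rot)
        if np.any(diag <= 0):
            raise ValueError(f"non-positive spacing in {path}")
        data = np.asarray(img.dataobj)
        return ImageVolume(data, tuple(diag), tuple(affine[:3, 3]))
    if path.suffix.lower() == ".mha":
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D image in {path}")
        if not np.allclose(np.asarray(img.GetDirection()).reshape(3, 3), np.eye(3)):
            raise ValueError(f"oblique direction matrix in {path} is unsupported")
        spacing = img.GetSpacing()
        if any(s <= 0 for s in spacing):
            raise ValueError(f"non-positive spacing in {path}")
        # SimpleITK arrays are (k, j, i); transpose to our (i, j, k) convention.
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return ImageVolume(data, spacing, img.GetOrigin())
    raise ValueError(f"unsupported image format: {path.name}")


def write_image(image: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` to NIfTI-1 or MetaImage, by extension."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(image.spacing)
        affine[:3, 3] = image.origin
        nib.save(nib.Nifti1Image(np.asarray(image.data), affine), str(path))
        return path
    if path.suffix.lower() == ".mha":
        img = sitk.GetImageFromArray(np.ascontiguousarray(image.data.transpose(2, 1, 0)))
        img.SetSpacing(image.spacing)
        img.SetOrigin(image.origin)
        sitk.WriteImage(img, str(path))
        return path
    raise ValueError(f"unsupported image format: {path.name}")


def read_labels(path: str | Path) -> LabelMap:
    img = read_image(path)
    return LabelMap(np.rint(img.data).astype(np.int32), img.spacing, img.origin)


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    return write_image(ImageVolume(labels.labels.astype(np.int16), labels.spacing, labels.origin), path)


def read_field(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    """Read a 3-component displacement field (mm); returns (u, spacing, origin)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 5:  # NIfTI vector convention (i, j, k, 1, 3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected a 3-component field in {path}")
    affine = img.affine
    return data, tuple(np.diag(affine[:3, :3])), tuple(affine[:3, 3])


def write_field(u: np.ndarray, spacing, origin, path: str | Path) -> Path:
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(u, dtype=np.float64), affine), str(path))
    return path


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmark pairs from a CSV with columns name,fx,fy,fz,mx,my,mz (mm)."""
    df = pd.read_csv(path)
    required = ["name", "fx", "fy", "fz", "mx", "my", "mz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns {missing}")
    for col in required[1:]:
        if len(df) and not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric coordinates in column {col!r}")
    return LandmarkSet(
        names=df["name"].astype(str).tolist(),
        fixed=df[["fx", "fy", "fz"]].to_numpy(dtype=float),
        moving=df[["mx", "my", "mz"]].to_numpy(dtype=float),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "name": landmarks.names,
            "fx": landmarks.fixed[:, 0], "fy": landmarks.fixed[:, 1], "fz": landmarks.fixed[:, 2],
            "mx": landmarks.moving[:, 0], "my": landmarks.moving[:, 1], "mz": landmarks.moving[:, 2],
        }
    )
    df.to_csv(path, index=False)
    return path


def load_config(path: str | Path | None = None, **overrides) -> RegistrationConfig:
    """Load a :class:`RegistrationConfig` from a YAML key-value file.

    Missing keys take the protocol defaults. Keyword overrides win over file
    values. Invariant violations are reported with the offending key.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(RegistrationConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    for key in ("B_s", "W_s"):
        if key in values:
            values[key] = tuple(values[key])
    try:
        return RegistrationConfig(**values)
    except ValueError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def read_rigid_transform(path: str | Path) -> RigidTransform:
    """Read a 4x4 rigid transform from a JSON or whitespace text file."""
    path = Path(path)
    if path.suffix == ".json":
        matrix = np.asarray(json.loads(path.read_text())["matrix"], dtype=float)
    else:
        matrix = np.loadtxt(path).reshape(4, 4)
    return RigidTransform(matrix)


# ---------------------------------------------------------------------------
# VTK legacy unstructured grid (ASCII) for tet meshes and metric fields.
# ---------------------------------------------------------------------------

def write_mesh_vtk(mesh, path: str | Path, point_tensors: np.ndarray | None = None) -> Path:
    """Write a tet mesh as a VTK legacy unstructured grid.

    The per-element tissue label goes into a cell-data array ``tissue``;
    optional per-vertex 3x3 tensors go into a point-data ``TENSORS`` block.
    """
    path = Path(path)
    v, t = mesh.vertices, mesh.tets
    lines = [
        "# vtk DataFile Version 3.0",
        "apbnrr tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(v)} double",
    ]
    lines += [" ".join(f"{x:.10g}" for x in p) for p in v]
    lines.append(f"CELLS {len(t)} {5 * len(t)}")
    lines += ["4 " + " ".join(str(i) for i in tet) for tet in t]
    lines.append(f"CELL_TYPES {len(t)}")
    lines += ["10"] * len(t)
    lines.append(f"CELL_DATA {len(t)}")
    lines.append("SCALARS tissue int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(x)) for x in mesh.tissue]
    if point_tensors is not None:
        tensors = np.asarray(point_tensors, dtype=float).reshape(len(v), 3, 3)
        lines.append(f"POINT_DATA {len(v)}")
        lines.append("TENSORS metric double")
        for m in tensors:
            for row in m:
                lines.append(" ".join(f"{x:.10g}" for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mesh_vtk(path: str | Path):
    """Read a tet mesh written by :func:`write_mesh_vtk`."""
    from .mesher import TetMesh

    tokens = Path(path).read_text().split()
    def _find(word: str, start: int = 0) -> int:
        return tokens.index(word, start)

    ip = _find("POINTS")
    n_pts = int(tokens[ip + 1])
    pts = np.array(tokens[ip + 3 : ip + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    ic = _find("CELLS")
    n_cells = int(tokens[ic + 1])
    raw = np.array(tokens[ic + 3 : ic + 3 + 5 * n_cells], dtype=int).reshape(n_cells, 5)
    if not np.all(raw[:, 0] == 4):
        raise ValueError("only tetrahedral cells are supported")
    tets = raw[:, 1:]
    tissue = np.ones(n_cells, dtype=int)
    try:
        it = _find("tissue")
        tissue = np.array(tokens[it + 5 : it + 5 + n_cells], dtype=int)
    except ValueError:
        pass
    return TetMesh(pts, tets, tissue)
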