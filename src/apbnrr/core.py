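"""Core domain types for the registration pipeline.

Geometry convention: images live on axis-aligned grids. A voxel index
``v = (i, j, k)`` (0-based) maps to the physical point (in millimetres)

    physical(v) = origin + v * spacing

with no direction matrix. All quantities downstream of I/O are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

BACKGROUND, PARENCHYMA, TUMOR = 0, 1, 2
LABEL_LEGEND = {BACKGROUND: "background", PARENCHYMA: "parenchyma", TUMOR: "tumor"}


@dataclass
class ImageVolume:
    """A 3D scalar image with axis-aligned physical geometry.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Scalar intensities indexed ``(i, j, k)``; must be finite.
    spacing : tuple of 3 floats
        Voxel size in mm along each axis; strictly positive.
    origin : tuple of 3 floats
        Physical position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image data contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def physical(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to physical mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel(self, points: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates (..., 3) to (fractional) voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of all voxel centers, shape (ni, nj, nk, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.physical(idx)

    def same_geometry(self, other: "ImageVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data, self.spacing, self.origin)


@dataclass
class LabelMap:
    """Integer segmentation on the same grid as a companion :class:`ImageVolume`.

    Legend: 0 background, 1 brain parenchyma, 2 tumor.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int32)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        unknown = set(np.unique(self.labels)) - set(LABEL_LEGEND)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}; legend is {LABEL_LEGEND}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def physical(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def brain_mask(self) -> np.ndarray:
        """Boolean mask of the cranial cavity (parenchyma + tumor)."""
        return self.labels > BACKGROUND

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return LabelMap(labels, self.spacing, self.origin)

    def matches(self, image: ImageVolume, atol: float = 1e-9) -> bool:
        return (
            self.shape == image.shape
            and np.allclose(self.spacing, image.spacing, atol=atol)
            and np.allclose(self.origin, image.origin, atol=atol)
        )


@dataclass
class RigidTransform:
    """A 4x4 homogeneous rigid transform (rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform must be a 4x4 matrix")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has negative determinant (reflection)")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        inv = np.eye(4)
        r = self.matrix[:3, :3]
        inv[:3, :3] = r.T
        inv[:3, 3] = -r.T @ self.matrix[:3, 3]
        return RigidTransform(inv)


# Search-window presets per case category (voxels), from the standard protocol.
WINDOW_PRESETS = {
    "BS": (7, 7, 3),
    "PR": (9, 9, 3),
    "TR": (13, 13, 3),
    "STR": (13, 13, 3),
}

CASE_TYPES = ("BS", "PR", "TR", "STR")


@dataclass
class RegistrationConfig:
    """Registration parameters.

    Defaults are the standard clinical protocol values: 5% of blocks
    selected under the "face" connectivity pattern, 3x3x3 blocks searched
    in a 7x7x3 window, mesh size delta = 5, brain parenchyma at 2.1 kPa
    and tumor at 21 kPa (both with Poisson ratio 0.45), 25% of outlier
    blocks rejected over 10 steps, at most 10 adaptive iterations, and an
    adaptive stop when fewer than 1% of selected blocks lack a
    correspondence.
    """

    F_s: float = 0.05                       # fraction of candidate blocks selected
    B_s: tuple[int, int, int] = (3, 3, 3)   # block size, voxels (odd)
    W_s: tuple[int, int, int] = (7, 7, 3)   # search window size, voxels
    pattern: str = "face"                   # block connectivity pattern
    delta: float = 5.0                      # mesh size (lattice pitch, voxels)
    E_b: float = 2100.0                     # Young's modulus, parenchyma (Pa)
    E_t: float = 21000.0                    # Young's modulus, tumor (Pa)
    V_b: float = 0.45                       # Poisson ratio, parenchyma
    V_t: float = 0.45                       # Poisson ratio, tumor
    F_r: float = 0.25                       # fraction of blocks rejected as outliers
    N_rej: int = 10                         # outlier rejection steps
    N_iter_max: int = 10                    # max adaptive iterations
    N_b0_min_frac: float = 0.01             # zero-correspondence stop fraction
    c_min: float = 0.85                     # zero-correspondence score threshold
    lambda_reg: float = 0.1                 # data/regularization balance
    resection_criterion: str = "both"       # zero_corr | intensity | both
    cavity_intensity_frac: float = 0.3      # cavity threshold vs median brain intensity
    subvoxel: bool = True                   # parabolic refinement of the NCC peak

    def __post_init__(self) -> None:
        self.B_s = tuple(int(b) for b in self.B_s)
        self.W_s = tuple(int(w) for w in self.W_s)
        if not 0 < self.F_s <= 1:
            raise ValueError(f"F_s must be in (0, 1], got {self.F_s}")
        if not 0 <= self.F_r < 1:
            raise ValueError(f"F_r must be in [0, 1), got {self.F_r}")
        if self.N_rej < 1:
            raise ValueError(f"N_rej must be >= 1, got {self.N_rej}")
        if any(w < b for w, b in zip(self.W_s, self.B_s)):
            raise ValueError(f"W_s {self.W_s} must be >= B_s {self.B_s} component-wise")
        if any(b % 2 == 0 or b < 1 for b in self.B_s):
            raise ValueError(f"B_s components must be odd positive, got {self.B_s}")
        for key in ("V_b", "V_t"):
            v = getattr(self, key)
            if not 0 <= v < 0.5:
                raise ValueError(f"{key} must be in [0, 0.5), got {v}")
        for key in ("E_b", "E_t"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be > 0")
        if self.pattern not in ("vertex", "edge", "face"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.N_iter_max < 1:
            raise ValueError("N_iter_max must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.resection_criterion not in ("zero_corr", "intensity", "both"):
            raise ValueError(f"unknown resection_criterion {self.resection_criterion!r}")
        if not 0 < self.cavity_intensity_frac < 1:
            raise ValueError("cavity_intensity_frac must be in (0, 1)")

    def with_case_type(self, case_type: str) -> "RegistrationConfig":
        """Return a copy using the search-window preset for a case category."""
        if case_type not in WINDOW_PRESETS:
            raise ValueError(f"unknown case type {case_type!r}; one of {CASE_TYPES}")
        return replace(self, W_s=WINDOW_PRESETS[case_type])


@dataclass
class LandmarkSet:
    """Paired anatomical landmarks (fixed/preoperative vs moving/intraoperative)."""

    names: list[str] = field(default_factory=list)
    fixed: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    moving: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.fixed = np.asarray(self.fixed, dtype=float).reshape(-1, 3)
        self.moving = np.asarray(self.moving, dtype=float).reshape(-1, 3)
        if not (len(self.names) == len(self.fixed) == len(self.moving)):
            raise ValueError("names, fixed, moving must have equal length")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate landmark names {dupes}")
        if not (np.all(np.isfinite(self.fixed)) and np.all(np.isfinite(self.moving))):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for n, f, m in zip(self.names, self.fixed, self.moving):
            yield n, f, m
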