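"""Synthetic brain phantoms with known ground truth.

Generates textured ellipsoidal "brain" volumes with an embedded spherical
tumor, deforms them through a smooth, invertible synthetic displacement
field (a sum of Gaussian radial bumps vanishing at the brain boundary),
and carves a dark resection cavity of controllable extent of resection
(EOR). The four clinical case categories are emulated as presets:
BS (brain shift only, EOR 0), PR (partial resection, 0.5), TR (total,
1.0) and STR (supra-total, 1.2, carving beyond the tumor).

All outputs are pure functions of (spec, seed). The default grid is
64^3 voxels at 2 mm spacing: desk-scale, yet leaving more than ten voxels
across the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from scipy import ndimage

from .core import BACKGROUND, PARENCHYMA, TUMOR, ImageVolume, LabelMap, LandmarkSet
from .fem import invert_field, _sample_field

CATEGORY_EOR = {"BS": 0.0, "PR": 0.5, "TR": 1.0, "STR": 1.2}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic case.

    Lengths in mm; the brain is an ellipsoid centered in the grid, the
    tumor a sphere strictly inside it.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semiaxes: tuple[float, float, float] = (50.0, 42.0, 46.0)
    tumor_center_offset: tuple[float, float, float] = (16.0, 0.0, 0.0)  # from brain center
    tumor_radius: float = 14.0
    texture_length: float = 12.0       # correlation length of the texture, mm
    texture_std: float = 8.0           # intensity std of the texture
    tumor_texture_frac: float = 0.2    # tumors are more homogeneous than parenchyma
    parenchyma_mean: float = 100.0
    tumor_mean: float = 170.0
    amplitude: float = 5.0             # max |u| of the synthetic deformation, mm
    n_bumps: int = 3
    eor: float = 0.0                   # extent of resection fraction, [0, 1.2]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.eor < 0:
            raise ValueError("eor must be >= 0")
        if not 1 <= self.n_bumps <= 5:
            raise ValueError("n_bumps must be in [1, 5]")
        # tumor strictly inside the brain ellipsoid
        off = np.asarray(self.tumor_center_offset, dtype=float)
        axes = np.asarray(self.brain_semiaxes, dtype=float)
        worst = np.sqrt((((np.abs(off) + self.tumor_radius) / axes) ** 2).sum())
        if worst >= 1.0:
            raise ValueError("tumor is not strictly inside the brain ellipsoid")

    @property
    def brain_center(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    @property
    def tumor_center(self) -> np.ndarray:
        return self.brain_center + np.asarray(self.tumor_center_offset)


@dataclass
class GroundTruth:
    """Known truth for validation: dense field, resection mask, landmarks."""

    u: np.ndarray                       # (ni, nj, nk, 3) forward displacement, mm
    resected: np.ndarray                # bool mask on the fixed grid (intraop space)
    landmarks: LandmarkSet
    tumor_mask_deformed: np.ndarray     # deformed (intraop-space) tumor mask
    analytic: Callable | None = None    # u at arbitrary mm points (not serialized)


def _ellipsoid_coordinate(points: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    return np.sqrt((((points - center) / axes) ** 2).sum(axis=-1))


def _anatomy(spec: PhantomSpec, factor: int = 2):
    """High-resolution anatomical intensity volume (factor x the image grid).

    Both the preoperative and intraoperative images are produced by one
    interpolation pass from this common anatomy, so neither is
    systematically sharper than the other (as with two native
    acquisitions). The anatomy combines band-limited random texture with
    deterministic structure — a dark ventricle-like ellipsoid and
    concentric sulcus-like dark laminae — giving the strong, repeatable
    intensity edges real brains present to edge metrics and block
    matching.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing)
    spacing_hi = spacing / factor
    # offset so image voxel centers fall mid-way between anatomy samples
    origin_hi = -spacing_hi / 2.0 + spacing_hi / 4.0
    shape_hi = tuple(int(n * factor) for n in spec.shape)
    grid = (np.stack(np.meshgrid(*[np.arange(n) for n in shape_hi], indexing="ij"),
                     axis=-1) * spacing_hi + origin_hi)

    axes = np.asarray(spec.brain_semiaxes)
    rho = _ellipsoid_coordinate(grid, spec.brain_center, axes)
    brain = rho <= 1.0
    tumor = np.linalg.norm(grid - spec.tumor_center, axis=-1) <= spec.tumor_radius

    noise = rng.standard_normal(shape_hi)
    sigma_vox = spec.texture_length / spacing_hi / 2.0
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    smooth *= spec.texture_std / max(smooth.std(), 1e-12)

    data = np.zeros(shape_hi)
    data[brain] = spec.parenchyma_mean + smooth[brain]
    # Sulcus-like concentric laminae: dark bands at fixed ellipsoidal radii,
    # of uniform physical width so their edge strength is uniform too.
    grad_rho = np.sqrt((((grid - spec.brain_center) / axes**2) ** 2).sum(axis=-1))
    grad_rho = grad_rho / np.maximum(rho, 0.05)
    half_width_mm = 4.0
    for rho0 in (0.3, 0.5, 0.7, 0.88):
        dist_mm = np.abs(rho - rho0) / np.maximum(grad_rho, 1e-6)
        band = np.clip(1.0 - (dist_mm / half_width_mm) ** 2, 0.0, None)
        data[brain] -= 50.0 * band[brain]

    def _blend(dist_mm: np.ndarray, width_mm: float = 1.5) -> np.ndarray:
        # C1 ramp 1 -> 0 across [-width, width] (inside negative)
        t = np.clip((width_mm - dist_mm) / (2 * width_mm), 0.0, 1.0)
        return t * t * (3 - 2 * t)

    # Ventricle-like dark ellipsoid medial to the tumor, smooth-profiled so
    # its edge strength is independent of the sampling offset.
    vent_center = spec.brain_center + np.array([-0.25, 0.0, 0.0]) * axes
    vent_axes = 0.22 * axes
    vr = _ellipsoid_coordinate(grid, vent_center, vent_axes)
    grad_vr = np.sqrt((((grid - vent_center) / vent_axes**2) ** 2).sum(axis=-1))
    grad_vr = grad_vr / np.maximum(vr, 0.05)
    vent_d = (vr - 1.0) / np.maximum(grad_vr, 1e-6)
    sv = _blend(vent_d)
    data[brain] = (1 - sv[brain]) * data[brain] + sv[brain] * (25.0 + 0.3 * smooth[brain])
    # Smooth-profiled tumor.
    tum_d = np.linalg.norm(grid - spec.tumor_center, axis=-1) - spec.tumor_radius
    st = _blend(tum_d)
    tumor_val = spec.tumor_mean + spec.tumor_texture_frac * smooth
    data[brain] = (1 - st[brain]) * data[brain] + st[brain] * tumor_val[brain]
    return data, origin_hi, spacing_hi


def _sample_anatomy(spec: PhantomSpec, points_mm: np.ndarray,
                    anatomy=None) -> np.ndarray:
    data_hi, origin_hi, spacing_hi = anatomy if anatomy is not None else _anatomy(spec)
    vox = (np.asarray(points_mm, dtype=float) - origin_hi) / spacing_hi
    flat = vox.reshape(-1, 3)
    vals = ndimage.map_coordinates(data_hi, [flat[:, a] for a in range(3)],
                                   order=1, mode="constant", cval=0.0)
    return vals.reshape(vox.shape[:-1])


def make_brain_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelMap]:
    """Textured preoperative volume and its segmentation, deterministic in seed."""
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing)
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1) * spacing

    axes = np.asarray(spec.brain_semiaxes)
    rho = _ellipsoid_coordinate(grid, spec.brain_center, axes)
    brain = rho <= 1.0
    tumor = np.linalg.norm(grid - spec.tumor_center, axis=-1) <= spec.tumor_radius
    if not (tumor & brain).sum() == tumor.sum():
        raise ValueError("tumor is not inside the brain")

    data = _sample_anatomy(spec, grid)
    data[~brain] = 0.0
    labels = np.zeros(shape, dtype=np.int32)
    labels[brain] = PARENCHYMA
    labels[tumor] = TUMOR

    image = ImageVolume(data, tuple(spacing), (0.0, 0.0, 0.0))
    return image, LabelMap(labels, tuple(spacing), (0.0, 0.0, 0.0))


def _synthetic_field(spec: PhantomSpec):
    """Analytic displacement: Gaussian bumps tapered to zero at the brain shell.

    Broad bumps (widths 0.45-0.7 of the smallest brain semi-axis) emulate
    gravity/CSF-driven brain shift, which in the clinic extends over much
    of a hemisphere rather than being tightly localized. When the case has
    a resection (eor > 0) an additional radial collapse component pulls
    tissue toward the tumor center, strongest at the tumor surface and
    decaying over about one tumor radius — the deformation surgery itself
    induces around the cavity.
    """
    rng = np.random.default_rng(spec.seed + 1)
    axes = np.asarray(spec.brain_semiaxes)
    center = spec.brain_center
    n = spec.n_bumps
    # Bump centers inside 0.6 x brain; directions on the unit sphere.
    bump_rho = 0.6 * rng.uniform(0.2, 1.0, size=n)
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = center + dirs * bump_rho[:, None] * axes
    amps = rng.uniform(0.5, 1.0, size=(n, 1)) * rng.standard_normal((n, 3))
    amps /= np.maximum(np.linalg.norm(amps, axis=1, keepdims=True), 1e-12)
    sigmas = rng.uniform(0.6, 0.9, size=n) * axes.min()

    t_center = spec.tumor_center
    r_t = spec.tumor_radius
    sigma_c = 0.8 * r_t
    # Resection-induced collapse dominates clinical deformation in resection
    # cases, so it carries at least the weight of the global shift bumps.
    collapse = 1.2 * min(spec.eor, 1.0)
    # Brain shift is gravity-dominated and the clinical protocol's thick
    # slices (3-voxel search windows along z) presume small through-plane
    # motion; the synthetic field is correspondingly in-plane dominant.
    anisotropy = np.array([1.0, 1.0, 0.25])

    def raw(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        out = np.zeros(pts.shape)
        for m in range(n):
            r2 = ((pts - centers[m]) ** 2).sum(axis=-1)
            out += np.exp(-r2 / (2 * sigmas[m] ** 2))[..., None] * amps[m]
        if collapse > 0:
            delta = pts - t_center
            s = np.linalg.norm(delta, axis=-1)
            unit = delta / np.maximum(s, 1e-9)[..., None]
            # inward pull: linear inside the tumor, Gaussian decay outside
            g = np.where(s < r_t, s / r_t,
                         np.exp(-((s - r_t) / sigma_c) ** 2 / 2))
            out -= collapse * g[..., None] * unit
        out = out * anisotropy
        rho = _ellipsoid_coordinate(pts, center, axes)
        w = np.zeros(rho.shape)
        core = rho <= 0.6
        taper = (rho > 0.6) & (rho < 0.95)
        w[core] = 1.0
        w[taper] = np.cos((rho[taper] - 0.6) / 0.35 * np.pi / 2) ** 2
        return out * w[..., None]

    return raw


def deform_phantom(image: ImageVolume, labels: LabelMap, spec: PhantomSpec,
                   n_landmarks: int = 6) -> tuple[ImageVolume, GroundTruth]:
    """Deform the preoperative phantom through the synthetic field.

    The intraoperative image samples the common high-resolution anatomy
    through the forward field (max |u| scaled to ``spec.amplitude``, zero
    on and outside the brain boundary shell), so it carries the same
    interpolation signature as the preoperative image. The dense field is
    stored on the fixed grid; landmark pairs satisfy
    moving = fixed + u(fixed) exactly.
    """
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing)
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1) * spacing

    raw = _synthetic_field(spec)
    u_raw = raw(grid)
    max_raw = np.linalg.norm(u_raw, axis=-1).max()
    scale = 0.0 if spec.amplitude == 0 or max_raw == 0 else spec.amplitude / max_raw

    def analytic(points: np.ndarray) -> np.ndarray:
        return raw(np.asarray(points, dtype=float)) * scale

    u = u_raw * scale

    # Invertibility: Jacobian determinant of x + u(x) positive at brain voxels.
    if spec.amplitude > 0:
        jac = np.zeros(shape + (3, 3))
        for a in range(3):
            g = np.gradient(u[..., a], *spacing)
            for b in range(3):
                jac[..., a, b] = g[b]
        det = np.linalg.det(np.eye(3) + jac)
        if np.any(det[labels.brain_mask()] <= 0):
            raise ValueError(
                f"amplitude {spec.amplitude} mm makes the synthetic field "
                "non-invertible (Jacobian determinant <= 0 inside the brain)"
            )

    anatomy = _anatomy(spec)
    brain = labels.brain_mask()
    if spec.amplitude > 0:
        v, _ = invert_field(u, spacing)
        intraop_data = _sample_anatomy(spec, grid - v, anatomy)
        tumor_def = _warp_mask(labels.labels == TUMOR, u, spacing)
    else:
        intraop_data = _sample_anatomy(spec, grid, anatomy)
        tumor_def = labels.labels == TUMOR
    intraop_data[~brain] = 0.0
    intraop = image.with_data(intraop_data)

    # Landmarks: deterministic interior points (inside the taper-free core).
    rng = np.random.default_rng(spec.seed + 2)
    axes = np.asarray(spec.brain_semiaxes)
    pts = []
    while len(pts) < n_landmarks:
        cand = spec.brain_center + rng.uniform(-0.5, 0.5, size=3) * axes
        if _ellipsoid_coordinate(cand, spec.brain_center, axes) < 0.55:
            pts.append(cand)
    fixed = np.asarray(pts)
    moving = fixed + analytic(fixed)
    names = [chr(ord("A") + i) for i in range(n_landmarks)]
    landmarks = LandmarkSet(names, fixed, moving)

    truth = GroundTruth(
        u=u,
        resected=np.zeros(shape, dtype=bool),
        landmarks=landmarks,
        tumor_mask_deformed=tumor_def,
        analytic=analytic,
    )
    return intraop, truth


def _warp_mask(mask: np.ndarray, u: np.ndarray, spacing) -> np.ndarray:
    """Push a fixed-grid boolean mask through the forward field (nearest)."""
    v, _ = invert_field(u, spacing)
    shape = mask.shape
    grid_vox = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    sample_vox = grid_vox - v / np.asarray(spacing)
    warped = ndimage.map_coordinates(mask.astype(float),
                                     [sample_vox[..., a] for a in range(3)],
                                     order=0, mode="constant", cval=0.0)
    return warped > 0.5


def resect_phantom(intraop: ImageVolume, labels: LabelMap, truth: GroundTruth,
                   eor: float, seed: int = 0) -> tuple[ImageVolume, GroundTruth]:
    """Carve a resection cavity of volume ``eor x deformed tumor volume``.

    The cavity grows outward from the deformed tumor centroid (for
    ``eor <= 1`` it stays within the deformed tumor; values up to 1.2 carve
    into surrounding parenchyma, emulating supra-total resection) and is
    filled with near-background noise. The achieved volume is exact to the
    voxel.
    """
    if eor < 0:
        raise ValueError("eor must be >= 0")
    tumor = truth.tumor_mask_deformed
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("no deformed tumor voxels to resect")
    n_target = int(round(eor * n_tumor))
    out = intraop.with_data(intraop.data.copy())
    cavity = np.zeros(intraop.shape, dtype=bool)
    if n_target > 0:
        spacing = np.asarray(intraop.spacing)
        grid = np.stack(np.meshgrid(*[np.arange(n) for n in intraop.shape], indexing="ij"),
                        axis=-1) * spacing
        centroid = grid[tumor].mean(axis=0)
        if n_target <= n_tumor:
            idx = np.argwhere(tumor)
            d = np.linalg.norm(grid[tumor] - centroid, axis=1)
            order = np.argsort(d, kind="stable")
            sel = idx[order[:n_target]]
        else:
            # whole tumor plus the nearest surrounding voxels by distance to it
            dist = ndimage.distance_transform_edt(~tumor, sampling=intraop.spacing)
            outside = np.argwhere(~tumor)
            d_out = dist[~tumor]
            order = np.argsort(d_out, kind="stable")
            extra = outside[order[: n_target - n_tumor]]
            sel = np.concatenate([np.argwhere(tumor), extra], axis=0)
        cavity[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        # Dark, nearly-flat fill: faint noise keeps block variance nonzero
        # (so correlation scores are defined, and low) without introducing
        # spurious edges inside the cavity.
        rng = np.random.default_rng(seed + 3)
        out.data[cavity] = np.abs(4.0 + rng.normal(0.0, 2.0, size=int(cavity.sum())))
    new_truth = GroundTruth(
        u=truth.u,
        resected=cavity,
        landmarks=truth.landmarks,
        tumor_mask_deformed=truth.tumor_mask_deformed,
        analytic=truth.analytic,
    )
    return out, new_truth


def make_case(case_type: str = "TR", spec: PhantomSpec | None = None):
    """Full phantom case for a clinical category (BS / PR / TR / STR).

    Returns (preop, labels, intraop, truth); the category fixes the EOR
    preset unless an explicit PhantomSpec overrides it.
    """
    if case_type not in CATEGORY_EOR:
        raise ValueError(f"unknown case type {case_type!r}")
    if spec is None:
        spec = PhantomSpec(eor=CATEGORY_EOR[case_type])
    preop, labels = make_brain_phantom(spec)
    intraop, truth = deform_phantom(preop, labels, spec)
    if spec.eor > 0:
        intraop, truth = resect_phantom(intraop, labels, truth, spec.eor, seed=spec.seed)
    return preop, labels, intraop, truth
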