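"""Registration models.

:class:`PBNRR` fits a linear-elastic finite-element brain model to sparse
block-matching displacements between a preoperative (moving) and an
intraoperative (fixed) image. :class:`AdaptivePBNRR` wraps it in the
adaptive outer loop that detects the resection cavity from
zero-correspondence evidence, excises tumor elements, re-tessellates, and
stops when the evidence is exhausted or the iteration cap is reached.

Both ``fit()`` methods return a results object carrying the nodal and
dense displacement fields, the warped preoperative image, diagnostics and
a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .blockmatch import (SparseDisplacementField, block_relevance,
                         flag_zero_correspondence, match_blocks, select_blocks)
from .core import (BACKGROUND, TUMOR, ImageVolume, LabelMap, RegistrationConfig,
                   RigidTransform)
from .fem import dense_field, extrapolate_field, register_pbnrr, warp_image
from .mesher import TetLocator, TetMesh, build_mesh, rasterize_inside_mask, retessellate


def estimate_resection_elements(mesh: TetMesh, field: SparseDisplacementField,
                                U: np.ndarray, locator: TetLocator | None = None) -> np.ndarray:
    """Tumor-tissue tets containing a displaced zero-correspondence block center.

    Block centers are displaced by the interpolated nodal solution before
    containment testing; parenchyma tets are never returned (removal is
    restricted to the segmented tumor).
    """
    if locator is None:
        locator = TetLocator(mesh)
    flagged = np.where(field.zero_correspondence)[0]
    if len(flagged) == 0:
        return np.empty(0, dtype=np.int64)
    centers = field.centers_mm[flagged]
    tet0, bary0 = locator.locate(centers)
    disp = np.zeros_like(centers)
    inside0 = tet0 >= 0
    if inside0.any():
        nodal = np.asarray(U).reshape(-1, 3)
        disp[inside0] = np.einsum("pj,pjc->pc", bary0[inside0], nodal[mesh.tets[tet0[inside0]]])
    tet_idx, _ = locator.locate(centers + disp)
    hit = tet_idx[tet_idx >= 0]
    hit = np.unique(hit)
    return hit[mesh.tissue[hit] == TUMOR]


def estimate_resection_elements_intensity(mesh: TetMesh, fixed: ImageVolume,
                                          U: np.ndarray, brain_median: float,
                                          frac: float = 0.3) -> np.ndarray:
    """Tumor tets whose displaced location is dark in the intraoperative image.

    A tumor element whose (displaced) interior samples a median
    intraoperative intensity below ``frac x brain_median`` maps into the
    resection cavity: the bright tumor it models no longer exists there.
    Complements the zero-correspondence evidence, whose spatial density is
    limited by the block-selection pattern.
    """
    from scipy import ndimage as ndi

    tumor_ids = np.where(mesh.tissue == TUMOR)[0]
    if len(tumor_ids) == 0:
        return tumor_ids
    nodal = np.asarray(U).reshape(-1, 3)
    coords = mesh.tet_coords()[tumor_ids]
    disp = nodal[mesh.tets[tumor_ids]]  # (m, 4, 3)
    # samples: displaced vertices, centroid and mid vertex-centroid points
    moved = coords + disp
    cent = moved.mean(axis=1, keepdims=True)
    samples = np.concatenate([moved, cent, 0.5 * (moved + cent)], axis=1)
    vox = (samples.reshape(-1, 3) - np.asarray(fixed.origin)) / np.asarray(fixed.spacing)
    vals = ndi.map_coordinates(np.asarray(fixed.data, dtype=float), vox.T,
                               order=1, mode="nearest")
    med = np.median(vals.reshape(len(tumor_ids), -1), axis=1)
    return tumor_ids[med < frac * brain_median]


@dataclass
class PBNRRResults:
    """PBNRR fit results: displacements, warped image and diagnostics."""

    model: "PBNRR"
    mesh: TetMesh
    field: SparseDisplacementField
    U: np.ndarray                 # nodal displacements (n, 3) mm
    dense_u: np.ndarray           # (ni, nj, nk, 3) mm on the fixed grid
    inside_mask: np.ndarray
    warped: ImageVolume
    trace: dict

    @property
    def max_displacement_mm(self) -> float:
        return float(np.linalg.norm(self.U, axis=1).max()) if len(self.U) else 0.0

    def summary(self) -> str:
        f = self.trace.get("final", {})
        lines = [
            "Physics-based non-rigid registration (PBNRR)",
            "=" * 52,
            f"mesh: {self.mesh.n_vertices} vertices, {self.mesh.n_tets} tets "
            f"({int((self.mesh.tissue == TUMOR).sum())} tumor)",
            f"blocks: {len(self.field)} matched, "
            f"{int(self.field.zero_correspondence.sum())} zero-correspondence, "
            f"{int(self.field.active.sum())} active after rejection",
            f"final RMS block error: {f.get('rms_error_mm', float('nan')):.3f} mm",
            f"max nodal displacement: {self.max_displacement_mm:.3f} mm",
        ]
        return "\n".join(lines)


@dataclass
class AdaptiveTrace:
    """Per-iteration record of the adaptive loop."""

    iterations: list = dc_field(default_factory=list)
    stop_reason: str = ""
    aborted: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def cumulative_resected_mm3(self) -> float:
        return self.iterations[-1]["cumulative_resected_mm3"] if self.iterations else 0.0


@dataclass
class AdaptiveResults(PBNRRResults):
    adaptive_trace: AdaptiveTrace = None

    def summary(self) -> str:
        t = self.adaptive_trace
        lines = [
            "Adaptive physics-based non-rigid registration (A-PBNRR)",
            "=" * 56,
            f"iterations: {t.n_iterations} (stop: {t.stop_reason})",
            f"cumulative resected model volume: {t.cumulative_resected_mm3:.0f} mm^3",
        ]
        for it in t.iterations:
            lines.append(
                f"  iter {it['iteration']}: {it['n_selected']} blocks, "
                f"{it['n_zero_correspondence']} zero-corr, "
                f"{it['n_elements_removed']} tets removed"
            )
        lines.append(f"max nodal displacement: {self.max_displacement_mm:.3f} mm")
        return "\n".join(lines)


class PBNRR:
    """Physics-based non-rigid registration of a preoperative image.

    Parameters
    ----------
    fixed : ImageVolume
        The intraoperative image (the target scene).
    moving : ImageVolume
        The preoperative image, rigidly pre-aligned to the fixed grid
        (or supply ``rigid`` to resample it once before registration).
    labels : LabelMap
        Segmentation of the moving image (0 background, 1 parenchyma, 2 tumor).
    config : RegistrationConfig, optional
    rigid : RigidTransform, optional
        Precomputed rigid initialization mapping moving to fixed space.
    """

    def __init__(self, fixed: ImageVolume, moving: ImageVolume, labels: LabelMap,
                 config: RegistrationConfig | None = None,
                 rigid: RigidTransform | None = None):
        self.config = config or RegistrationConfig()
        if rigid is not None:
            moving = _resample_rigid(moving, fixed, rigid)
        if not fixed.same_geometry(moving):
            raise ValueError("fixed and moving images must share the grid "
                             "(supply a rigid transform to resample)")
        if not labels.matches(moving):
            raise ValueError("label map must share the moving image grid")
        self.fixed = fixed
        self.moving = moving
        self.labels = labels

    def _match(self, labels: LabelMap, c_min: float | None = None):
        """Select, match and flag blocks on the given model support.

        ``c_min=None`` flags only blocks with an undefined correlation:
        plain PBNRR predates the zero-correspondence concept and feeds
        every matched block to the solve (cavity mismatches included),
        relying on the outlier-rejection schedule alone — which is why it
        degrades in the presence of resection. The adaptive method passes
        the configured score threshold.
        """
        cfg = self.config
        rel = block_relevance(self.moving, labels.brain_mask(), cfg.B_s)
        blocks = select_blocks(rel, cfg.F_s, cfg.pattern, cfg.B_s)
        field = match_blocks(self.moving, self.fixed, blocks, cfg.W_s,
                             subvoxel=cfg.subvoxel)
        field, n_zero = flag_zero_correspondence(
            field, -1.0 if c_min is None else c_min)
        return blocks, field, n_zero

    def fit(self) -> PBNRRResults:
        cfg = self.config
        mesh = build_mesh(self.labels, cfg.delta)
        _, field, _ = self._match(self.labels)
        locator = TetLocator(mesh)
        U, field, trace = register_pbnrr(mesh, field, cfg, locator)
        u, inside = dense_field(mesh, U, self.fixed)
        warped = warp_image(self.moving, u)
        return PBNRRResults(self, mesh, field, U, u, inside, warped, trace)


class AdaptivePBNRR(PBNRR):
    """A-PBNRR: PBNRR with iterative resection-cavity excision.

    Each iteration re-selects and matches blocks on the current model
    support, solves the PBNRR system, flags zero-correspondence blocks,
    removes tumor elements containing displaced flagged centers, and
    re-tessellates. The loop stops at ``N_iter_max`` iterations, when the
    zero-correspondence count falls below ``N_b0_min_frac`` of selected
    blocks, or when no elements were removed in an iteration.
    """

    def _resection_elements(self, mesh, field, U, locator, brain_median):
        cfg = self.config
        ids = []
        if cfg.resection_criterion in ("zero_corr", "both"):
            ids.append(estimate_resection_elements(mesh, field, U, locator))
        if cfg.resection_criterion in ("intensity", "both"):
            ids.append(estimate_resection_elements_intensity(
                mesh, self.fixed, U, brain_median, cfg.cavity_intensity_frac))
        return np.unique(np.concatenate(ids)) if ids else np.empty(0, dtype=np.int64)

    def fit(self) -> AdaptiveResults:
        cfg = self.config
        labels = self.labels.with_labels(self.labels.labels.copy())
        brain_median = float(np.median(self.moving.data[self.labels.brain_mask()]))
        atrace = AdaptiveTrace()
        cumulative = 0.0
        last = None  # (mesh, field, U, trace)

        for iteration in range(cfg.N_iter_max):
            try:
                mesh = build_mesh(labels, cfg.delta)
            except ValueError as exc:
                atrace.aborted = True
                atrace.stop_reason = f"re-tessellation failed: {exc}"
                break
            _, field, n_zero = self._match(labels, cfg.c_min)
            locator = TetLocator(mesh)
            U, field, trace = register_pbnrr(mesh, field, cfg, locator)
            last = (mesh, field, U, trace)

            record = {
                "iteration": iteration,
                "n_selected": len(field),
                "n_zero_correspondence": n_zero,
                "n_elements_removed": 0,
                "cumulative_resected_mm3": cumulative,
                "n_vertices": mesh.n_vertices,
                "n_tets": mesh.n_tets,
            }
            threshold = int(np.ceil(cfg.N_b0_min_frac * len(field)))
            if n_zero < threshold:
                atrace.iterations.append(record)
                atrace.stop_reason = (
                    f"zero-correspondence count {n_zero} below threshold {threshold}"
                )
                break

            tet_ids = self._resection_elements(mesh, field, U, locator, brain_median)
            if len(tet_ids) == 0:
                atrace.iterations.append(record)
                atrace.stop_reason = "no elements removed"
                break

            removed_volume = float(np.abs(TetMesh(
                mesh.vertices, mesh.tets[tet_ids], mesh.tissue[tet_ids]
            ).volumes()).sum())
            cumulative += removed_volume
            record["n_elements_removed"] = len(tet_ids)
            record["cumulative_resected_mm3"] = cumulative
            atrace.iterations.append(record)

            # Relabel voxels inside removed elements as background (cavity).
            removed = TetMesh(mesh.vertices, mesh.tets[tet_ids], mesh.tissue[tet_ids])
            cavity = rasterize_inside_mask(removed, labels)
            new_labels = labels.labels.copy()
            new_labels[cavity] = BACKGROUND
            if not (new_labels > BACKGROUND).any():
                atrace.stop_reason = "model exhausted"
                break
            labels = labels.with_labels(new_labels)
        else:
            atrace.stop_reason = f"reached N_iter_max = {cfg.N_iter_max}"

        if last is None:
            raise RuntimeError("adaptive registration produced no solve")
        mesh, field, U, trace = last
        u, inside = dense_field(mesh, U, self.fixed)
        # Excised elements leave the cavity without field support; carry the
        # rim displacement into it so the whole preoperative brain is mapped.
        u, inside = extrapolate_field(u, inside, self.labels.brain_mask())
        warped = warp_image(self.moving, u)
        res = AdaptiveResults(self, mesh, field, U, u, inside, warped, trace)
        res.adaptive_trace = atrace
        return res


def _resample_rigid(moving: ImageVolume, fixed: ImageVolume,
                    rigid: RigidTransform) -> ImageVolume:
    """Resample the moving image once onto the fixed grid through the rigid map."""
    from scipy import ndimage

    pts = fixed.grid_points().reshape(-1, 3)
    src = rigid.inverse().apply(pts)
    vox = moving.voxel(src)
    data = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float),
        [vox[:, a].reshape(fixed.shape) for a in range(3)],
        order=1, mode="constant", cval=0.0,
    )
    return ImageVolume(data, fixed.spacing, fixed.origin)
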