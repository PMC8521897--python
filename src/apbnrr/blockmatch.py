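"""Feature-block selection and block matching.

Blocks of size ``B_s`` voxels are selected inside the cranial cavity by
decreasing intensity variance under a connectivity pattern, then matched
into the intraoperative image by exhaustive integer-offset search over a
``W_s`` window maximizing normalized cross-correlation (NCC). Blocks with
no usable correlation (constant intensity on either side, e.g. inside a
resection cavity) carry a zero-correspondence flag.

Pattern semantics ("vertex" strictest, "face" loosest):
  vertex - selected blocks may not touch at all (not even a corner);
  edge   - may share corners but not edges;
  face   - may share edges but not faces.
Overlapping blocks are forbidden under every pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .core import ImageVolume

# Contact codimension allowed per pattern: number of axes where the block
# boxes exactly touch. 0 = volume overlap, 1 = face, 2 = edge, 3 = corner.
_MAX_FORBIDDEN_CODIM = {"vertex": 3, "edge": 2, "face": 1}


@dataclass
class BlockSet:
    """Selected block centers (voxel indices on the fixed grid) and relevance."""

    centers: np.ndarray          # (n, 3) int voxel indices
    block_size: tuple[int, int, int]
    relevance: np.ndarray        # (n,)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.int64).reshape(-1, 3)
        self.relevance = np.asarray(self.relevance, dtype=float).reshape(-1)
        self.block_size = tuple(int(b) for b in self.block_size)

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class SparseDisplacementField:
    """Per-block matched displacements: the registration's data term."""

    centers_vox: np.ndarray   # (n, 3) int
    centers_mm: np.ndarray    # (n, 3) float
    displacements_mm: np.ndarray  # (n, 3) float
    scores: np.ndarray        # (n,) NCC in [-1, 1]; NaN where undefined
    zero_correspondence: np.ndarray  # (n,) bool
    active: np.ndarray        # (n,) bool, survives outlier rejection

    def __post_init__(self) -> None:
        self.centers_vox = np.asarray(self.centers_vox, dtype=np.int64).reshape(-1, 3)
        self.centers_mm = np.asarray(self.centers_mm, dtype=float).reshape(-1, 3)
        self.displacements_mm = np.asarray(self.displacements_mm, dtype=float).reshape(-1, 3)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        self.zero_correspondence = np.asarray(self.zero_correspondence, dtype=bool).reshape(-1)
        self.active = np.asarray(self.active, dtype=bool).reshape(-1)

    def __len__(self) -> int:
        return len(self.centers_vox)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.scores)

    def usable(self) -> np.ndarray:
        """Blocks that may drive the solve: active and with a correspondence."""
        return self.active & ~self.zero_correspondence


def block_relevance(image: ImageVolume, mask: np.ndarray, B_s=(3, 3, 3)) -> np.ndarray:
    """Block intensity variance at each candidate center; NaN where invalid.

    A candidate is a voxel whose ``B_s`` block lies fully inside both the
    image and the mask. ``B_s`` must be odd per axis.
    """
    B_s = tuple(int(b) for b in B_s)
    if any(b % 2 == 0 or b < 1 for b in B_s):
        raise ValueError(f"B_s must be odd positive per axis, got {B_s}")
    if any(b > n for b, n in zip(B_s, image.shape)):
        raise ValueError(f"B_s {B_s} larger than image {image.shape}")
    data = np.asarray(image.data, dtype=float)
    mean = ndimage.uniform_filter(data, size=B_s, mode="constant")
    mean2 = ndimage.uniform_filter(data * data, size=B_s, mode="constant")
    var = np.maximum(mean2 - mean * mean, 0.0)

    half = np.array([b // 2 for b in B_s])
    valid = ndimage.binary_erosion(
        np.asarray(mask, dtype=bool), structure=np.ones(B_s, dtype=bool), border_value=0
    )
    # block must also sit fully inside the image
    edge = np.zeros(image.shape, dtype=bool)
    edge[half[0]: image.shape[0] - half[0],
         half[1]: image.shape[1] - half[1],
         half[2]: image.shape[2] - half[2]] = True
    valid &= edge
    rel = np.where(valid, var, np.nan)
    return rel


def select_blocks(relevance: np.ndarray, F_s: float, pattern: str = "face",
                  B_s=(3, 3, 3)) -> BlockSet:
    """Greedy pattern-constrained selection of the most relevant blocks.

    Candidates are taken in decreasing relevance (ties broken
    lexicographically by voxel index); a candidate violating the pattern
    against an already-selected block is skipped. Selection stops at
    ``ceil(F_s * n_candidates)`` or exhaustion.
    """
    if not 0 < F_s <= 1:
        raise ValueError(f"F_s must be in (0, 1], got {F_s}")
    if pattern not in _MAX_FORBIDDEN_CODIM:
        raise ValueError(f"unknown pattern {pattern!r}")
    B = np.asarray([int(b) for b in B_s])
    rel = np.asarray(relevance, dtype=float)
    cand = np.argwhere(np.isfinite(rel))
    if len(cand) == 0:
        raise ValueError("no candidate blocks (empty or too-small mask)")
    values = rel[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -values))
    cand = cand[order]
    values = values[order]
    target = int(np.ceil(F_s * len(cand)))

    # Forbidden-offset kernel: contact with codimension <= threshold.
    thr = _MAX_FORBIDDEN_CODIM[pattern]
    off = np.stack(
        np.meshgrid(*[np.arange(-b, b + 1) for b in B], indexing="ij"), axis=-1
    )
    g = np.abs(off) - B  # per-axis gap; <=0 means touching or overlapping
    contact = np.all(g <= 0, axis=-1)
    codim = (g == 0).sum(axis=-1)
    kernel = contact & (codim <= thr)

    pad = B
    shape = np.asarray(rel.shape) + 2 * pad
    selected_map = np.zeros(tuple(shape), dtype=bool)
    chosen: list[int] = []
    for n in range(len(cand)):
        if len(chosen) >= target:
            break
        i, j, k = cand[n] + pad
        window = selected_map[i - B[0]: i + B[0] + 1,
                              j - B[1]: j + B[1] + 1,
                              k - B[2]: k + B[2] + 1]
        if np.any(window & kernel):
            continue
        selected_map[i, j, k] = True
        chosen.append(n)
    chosen = np.asarray(chosen, dtype=int)
    return BlockSet(cand[chosen], tuple(B), values[chosen])


def match_blocks(fixed_preop: ImageVolume, moving_intraop: ImageVolume,
                 blocks: BlockSet, W_s=(7, 7, 3),
                 subvoxel: bool = False) -> SparseDisplacementField:
    """Exhaustive integer-offset NCC matching of preoperative blocks.

    Each preoperative block is searched over a ``W_s`` window in the
    intraoperative image; the displacement is the offset maximizing NCC,
    converted to mm. Ties prefer the smallest |d|, then lexicographic
    offset. Offsets whose block would leave the image are clipped
    (skipped), never wrapped. Blocks with zero intensity variance on the
    fixed side, or with no offset of nonzero variance on the moving side,
    have an undefined score and are flagged zero-correspondence.

    With ``subvoxel=True`` the integer peak is refined per axis by a
    parabolic fit through the scores at the neighboring offsets (shift
    clamped to half a voxel); an exact integer peak with symmetric
    neighbors is left untouched.
    """
    W = np.asarray([int(w) for w in W_s])
    B = np.asarray(blocks.block_size)
    if np.any(W < B):
        raise ValueError(f"W_s {tuple(W)} must be >= B_s {tuple(B)} component-wise")
    half = B // 2
    radius = (W - B) // 2
    shape = np.asarray(fixed_preop.shape)
    spacing = np.asarray(fixed_preop.spacing)
    fixed = np.asarray(fixed_preop.data, dtype=float)
    moving = np.asarray(moving_intraop.data, dtype=float)

    # Offsets in deterministic tie-break order: |o|^2, then lexicographic.
    offs = np.stack(
        np.meshgrid(*[np.arange(-r, r + 1) for r in radius], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    key = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], (offs**2).sum(axis=1)))
    offs = offs[key]

    n = len(blocks)
    d_mm = np.zeros((n, 3))
    scores = np.full(n, np.nan)
    nblock = int(np.prod(B))
    for b in range(n):
        c = blocks.centers[b]
        f = fixed[c[0] - half[0]: c[0] + half[0] + 1,
                  c[1] - half[1]: c[1] + half[1] + 1,
                  c[2] - half[2]: c[2] + half[2] + 1].ravel()
        fc = f - f.mean()
        den_f = np.sqrt((fc * fc).sum())
        if den_f == 0:
            continue  # zero variance on the fixed side: undefined
        # Clipped search region in the moving image.
        lo_r = np.maximum(c - half - radius, 0)
        hi_r = np.minimum(c + half + radius, shape - 1)
        if np.any(hi_r - lo_r + 1 < B):
            continue
        region = moving[lo_r[0]: hi_r[0] + 1, lo_r[1]: hi_r[1] + 1, lo_r[2]: hi_r[2] + 1]
        win = sliding_window_view(region, tuple(B))
        flat = win.reshape(win.shape[0], win.shape[1], win.shape[2], nblock)
        mc = flat - flat.mean(axis=-1, keepdims=True)
        den_m = np.sqrt((mc * mc).sum(axis=-1))
        num = mc @ fc
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(den_m > 0, num / (den_m * den_f), np.nan)
        # Window position (a, b, c) corresponds to offset lo_r + (a,b,c) + half - c
        base = lo_r + half - c
        best = -np.inf
        best_off = None
        for o in offs:
            w = o - base
            if np.any(w < 0) or np.any(w >= np.asarray(ncc.shape)):
                continue
            s = ncc[w[0], w[1], w[2]]
            if np.isfinite(s) and s > best:
                best = s
                best_off = o
        if best_off is not None:
            scores[b] = best
            frac = np.zeros(3)
            # NCC of 1 means an exact (affine-identical) match at the integer
            # offset; refinement would only chase noise.
            if subvoxel and best < 0.999:
                w0 = best_off - base
                for a in range(3):
                    if radius[a] == 0:
                        continue
                    wl, wh = w0.copy(), w0.copy()
                    wl[a] -= 1
                    wh[a] += 1
                    if np.any(wl < 0) or np.any(wh >= np.asarray(ncc.shape)):
                        continue
                    sl, sh = ncc[tuple(wl)], ncc[tuple(wh)]
                    if not (np.isfinite(sl) and np.isfinite(sh)):
                        continue
                    denom = sl - 2 * best + sh
                    if denom < -1e-12:
                        frac[a] = np.clip(0.5 * (sl - sh) / denom, -0.5, 0.5)
            d_mm[b] = (best_off + frac) * spacing
    defined = np.isfinite(scores)
    return SparseDisplacementField(
        centers_vox=blocks.centers,
        centers_mm=fixed_preop.physical(blocks.centers),
        displacements_mm=d_mm,
        scores=scores,
        zero_correspondence=~defined,
        active=np.ones(n, dtype=bool),
    )


def flag_zero_correspondence(field: SparseDisplacementField, c_min: float = 0.5):
    """Flag blocks whose score is undefined or below ``c_min``.

    Returns the updated field and the flagged count.
    """
    with np.errstate(invalid="ignore"):
        flagged = ~field.defined | (field.scores < c_min)
    out = replace(field, zero_correspondence=flagged)
    return out, int(flagged.sum())
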