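# Methods

This note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not establish.

## Registration model

### Data term: block matching

Feature blocks of `B_s = 3×3×3` voxels are candidates at every voxel whose
block lies fully inside the cranial-cavity mask. Relevance is the block's
intensity variance. Selection is greedy in decreasing relevance (ties broken
lexicographically by voxel index) under a connectivity pattern on the block
boxes: *vertex* forbids any contact between selected blocks, *edge* allows
corner contact, *face* (the default) also allows edge contact but forbids
face contact and overlap. Under these semantics the face pattern jams at
roughly 1–2 % of candidates, so the nominal `F_s = 5 %` budget is typically
exhausted by the constraint rather than met; selection stops at
`⌈F_s·n⌉` or exhaustion, whichever comes first.

Each selected preoperative block is searched over a `W_s` window in the
intraoperative image by exhaustive integer offsets maximizing normalized
cross-correlation (ties prefer the smallest displacement, then
lexicographic offset; windows are clipped at the image border, never
wrapped). `W_s` follows the case category: 7×7×3 for pure brain shift,
9×9×3 for partial and 13×13×3 for total/supra-total resections — the
3-voxel z-extent encodes a thick-slice protocol in which through-plane
motion is not searched.

**Subvoxel refinement** (`RegistrationConfig.subvoxel`, default on) fits a
per-axis parabola through the correlation scores at the neighboring integer
offsets and shifts the peak by up to half a voxel. At 2 mm phantom voxels a
≤5 mm smooth field is barely one voxel of displacement, so integer-only
matching quantizes most of the signal away; refinement is skipped whenever
the integer peak is an exact match (NCC ≥ 0.999), which keeps the
zero-deformation and pure-translation oracles exact. The low-level
`match_blocks` keeps `subvoxel=False` as its own default so the integer
contract remains exactly testable.

**Zero-correspondence flagging.** A block is flagged when its score is
undefined (zero variance on either side) or below `c_min`. The default is
`c_min = 0.85`: for 27-voxel blocks, the null distribution of NCC maximized
over a search window for *unrelated* content concentrates at 0.6–0.8
(measured on resection phantoms: cavity blocks score 0.52–0.88), while
genuine tissue matches score ≈ 0.95–1.0, so the threshold must sit above
the null, not at 0.5. Plain PBNRR predates the zero-correspondence concept:
it excludes only undefined-score blocks and relies on outlier rejection,
which is part of why it degrades under resection.

### Mechanical term: linear-elastic FEM

The label map is tessellated (below) into a two-tissue P1 tetrahedral model
with isotropic linear elasticity: parenchyma `E_b = 2.1 kPa`, tumor
`E_t = 21 kPa`, Poisson ratio 0.45 for both. Only the stiffness *ratio*
matters in the approximation problem, so the solver uses the dimensionless
stiffness `K̂ = K / (E_b · h̄)` with `h̄` the mean edge length. The nodal
displacement solves

    (λ K̂ + HᵀSH) U = HᵀS D

with `H` the barycentric interpolation of nodal values at block centers and
`S = s·I₃` per block (the NCC score, floored at 10⁻⁶). The default
`λ = 0.1` weights elastic smoothing an order below data fidelity at matched
points; rigid translations lie in the null space of `K`, so constant
displacements are recovered exactly for any `λ`.

**Outlier rejection** trims `⌊F_r·N₀⌋` of the initially active blocks over
`N_rej` steps (`⌊·⌋` per step, remainder in the last; ties deactivate the
larger block index first), re-solving after each step. With 100 blocks,
`F_r = 0.25`, `N_rej = 10`, exactly 75 remain. The trimmed objective is
non-increasing across steps (fewer nonnegative terms, re-optimized).

### Adaptive loop (A-PBNRR)

Each iteration: select and match blocks on the current model support, solve
PBNRR, detect resected tumor elements, excise and re-tessellate. Detection
(`resection_criterion`, default `"both"`) combines

* the zero-correspondence rule: tumor-tissue elements containing a flagged
  block center after displacement by the current solution (parenchyma
  elements are never removed); and
* an intensity rule: tumor elements whose displaced interior samples a
  median intraoperative intensity below `cavity_intensity_frac = 0.3` of
  the median preoperative brain intensity — the bright tumor the element
  models no longer exists there.

The intensity rule is enabled by default because the pattern-constrained
block density (~1 % of voxels) leaves the zero-correspondence evidence too
sparse to excise more than ~20 % of a typical cavity on its own; combined,
the loop recovers 75–95 % of the true cavity volume in 2–7 iterations on
total-resection phantoms. The loop stops at `N_iter_max = 10`, when the
zero-correspondence count falls below `⌈N_b0_min_frac · n_selected⌉`
(default 1 %), or when an iteration removes nothing (a termination guard
beyond the two configured criteria, logged distinctly in the trace).

The final dense field is P1-interpolated at voxel centers; because excised
elements leave the cavity without support, the adaptive model extrapolates
the rim displacement into the remaining brain mask (nearest-neighbor) so
the entire preoperative brain is mapped. Plain PBNRR's field stays zero
outside its mesh.

### Warping

`warp_image` resamples the moving image as `out(x) = moving(x − v(x))`
where `v` is the fixed-point inverse of the forward field (tolerance 0.1
voxel, ≤ 20 iterations, nearest-extension sampling at the grid border to
avoid boundary flip-flop); non-convergent voxels are counted and filled.

## Meshing

A body-centered-cubic lattice at pitch `delta` voxels (default 5) is
tessellated into four congruent tetrahedra per face-adjacent cell pair.
Elements whose centroid lies in the labeled region are kept; boundary
vertices within 0.9 pitch of the segmentation surface are projected onto
the interpolated zero level of the signed distance (fixed-point, 4 steps),
applied one vertex at a time with step halving and reversion whenever an
incident element would degenerate or invert. Tissue labels are the majority
of nine per-element samples (vertices, centroid, vertex–centroid
midpoints); ties go to parenchyma. Smaller `delta` produces strictly more
elements. On cubes, spheres and the default phantom the mesh covers ≥ 95 %
of the labeled volume with ≤ 5 % spillover; boundary projection can create
small dihedral angles (a few degrees), which the direct sparse solver
tolerates. This lattice mesher is a deliberately simple, deterministic
stand-in for Delaunay image-to-mesh conversion; it trades boundary
fidelity guarantees for exact reproducibility.

## Mesh adaptation metrics

The goal is to equidistribute registration points over vertex cell
complexes. Isotropic metric: `M_v = I / d_k(v)²` with `d_k` the distance to
the k-th nearest registration point (clinical default `k = 500`; phantoms
use `min(500, n/2)` since they yield far fewer points). Anisotropic metric:
the minimum-volume ellipsoid centered at the vertex enclosing its k nearest
points, computed by Khachiyan iteration on the centrally symmetrized set
(`ε = 10⁻³`, ≤ 10⁴ iterations; degenerate configurations are regularized
with a minimum axis length); the inflation constant `a ≥ 1` scales every
axis, i.e. divides the tensor by `a²`, so ellipsoids nest monotonically
in `a`. Refinement is conforming longest-metric-edge bisection (edges with
averaged-metric length > √2 split at midpoints, metrics interpolated,
size-capped at 10× the input), a refinement-only substitute for full
anisotropic remeshing: its acceptance is the equidistribution property (the
variance of points per vertex cell drops by ~4× on clustered sets), not
clinical mesh statistics.

## Evaluation

3D Canny: Gaussian smoothing (σ = 1 voxel), gradient non-maximum
suppression along the interpolated gradient direction, hysteresis on a
26-connected weak-edge graph seeded by strong edges, and subpixel edge
localization by a parabolic fit of the magnitude profile along the gradient
(clamped to half a voxel) — without it, untransformed point sets sit on the
voxel lattice and percentile distances cluster at lattice values. Default
thresholds are the 70th/90th percentile of gradient magnitude inside the
mask; the phantom case evaluation (`case_hd`) instead uses absolute
thresholds between the phantom's texture gradients (< ~4 intensity
units/mm) and its anatomical-edge gradients (~10–15/mm), because adaptive
percentiles chase weak texture whose edge membership is not reproducible
between two acquisitions of the same anatomy.

The Hausdorff distance is `max(h(A,B), h(B,A))` with `h` the given
percentile (100 = classical) of nearest-neighbor distances. Phantom method
comparisons use the 95th percentile: at desk scale the absolute maximum is
dominated by single-point edge-membership noise rather than registration
error (the 95 % variant is an established choice in this literature).
Landmark errors are distances between field-transformed preoperative
landmarks and their intraoperative partners, aggregated min/max/mean.

`summarize` reproduces the published 30-case table arithmetic exactly:
ratios and averages are rounded half-away-from-zero to two decimals (one
printed ratio is an exact decimal half, which half-even rounding would
miss).

## Phantom generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment. A 64³ grid at 2 mm spacing holds an ellipsoidal brain
(semi-axes 50/42/46 mm) with a 14 mm-radius spherical tumor offset 16 mm
from center. Anatomy is built at 2× resolution and both images are produced
by one trilinear sampling pass from it — the preoperative at the identity,
the intraoperative through the deformation — so neither image is
systematically sharper (as with two native acquisitions). Appearance:
band-limited texture (12 mm correlation, σ = 8, strictly above the sampling
scale so resampling offsets do not alias it), parenchyma mean 100, a
homogeneous bright tumor (mean 170, 0.2× texture), a dark ventricle-like
ellipsoid and four concentric sulcus-like dark laminae of uniform physical
width — the strong, repeatable internal edges real brains present to edge
metrics and block matching.

Deformation: three Gaussian bumps of width 0.6–0.9× the smallest semi-axis
(broad, gravity/CSF-like shift) plus, for resection cases, a radial
collapse toward the tumor center (linear inside the tumor, Gaussian decay
over 0.8 radii outside) weighted 1.2× the bump scale — clinically,
resection-induced deformation dominates. The field is scaled so its maximum
is `amplitude` (default 5 mm), tapered to zero across the outer brain
shell, made in-plane dominant (z × 0.25, matching the thick-slice protocol
regime), and verified invertible (Jacobian determinant > 0 at every brain
voxel). Landmarks are six interior points with `moving = fixed + u(fixed)`
exact by construction.

Resection carves the cavity in intraoperative space (after deformation):
voxels of the deformed tumor nearest its centroid, exactly
`round(eor × volume)` of them; `eor > 1` continues into the surrounding
parenchyma (supra-total). The fill is dark near-flat noise (mean 4, σ = 2):
faint enough to yield no edge points, yet nonzero-variance so correlation
scores are defined (and low). Category presets: BS 0, PR 0.5, TR 1.0,
STR 1.2.

**What passing phantom tests do not show:** real MR artifacts (bias fields,
noise correlation, partial-volume effects), real brain geometry and
heterogeneity, deformation from retraction or swelling, segmentation error
(labels are exact here), or clinical deformation magnitudes an order larger
than the search window — the iterative capture-range advantage of the
adaptive method is therefore not exercised, only its resection handling.

## Surrogate

A 14-feature regressor (12 registration parameters — `F_s`, `B_s`, `W_s`,
`delta`, the tumor:brain stiffness ratio, `F_r`, `N_rej`, `c_min` — plus a
lobe-wise tumor-location code from a fixed dictionary and the rigid
registration error in mm) predicts the Hausdorff distance a run would
achieve. Four hidden layers of 128 rectified-linear units, one linear
output; SGD with Nesterov momentum 0.9, batch 256, 200 epochs, learning
rate 10⁻² (chosen for full convergence within the epoch budget; inputs and
target are standardized on the training split). Train/evaluation splits are
by case id and mutually exclusive. Run logging is CSV-backed and idempotent
by input hash. Desk-scale benchmarks use synthetic parameter-to-error
landscapes of 5–20 k rows; the clinical regime (millions of runs) is out of
scope.

## Problem sizes

Default experiments: 64³ phantoms (≈ 4 900 tets, ≈ 500 blocks, ≈ 12 k
degrees of freedom; one PBNRR fit ≈ 5 s, an adaptive fit 10–30 s), 20-point
ellipsoid benchmarks, 360-point equidistribution sets, 20 k-row surrogate
datasets. The acceptance script averages the resection comparison over six
phantom replicates; everything completes in a few minutes on one CPU.

## Known limitations

* The block-selection pattern semantics are an interpretation; under them
  the 5 % selection budget is unreachable (jamming at ~1–2 %), which is why
  the intensity-based resection criterion is needed alongside the
  zero-correspondence rule.
* Through-plane displacement is unobservable under the 3-voxel z windows;
  fields with substantial z components are only partially recoverable.
* The mesher is refinement-oriented and can emit slivers near curved
  boundaries; quality is reported, not guaranteed.
* Metric-driven adaptation only refines; coarsening and anisotropic
  quality optimization are not implemented.
* The rigid initialization is consumed, never computed.
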