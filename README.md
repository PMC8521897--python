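# apbnrr — adaptive physics-based non-rigid registration of brain MRI

During neurosurgery the brain deforms — cerebrospinal-fluid loss, gravity,
and above all the resection of the tumor itself — so a rigid mapping of
preoperative MRI (and the fMRI/DTI plans registered to it) onto the
intraoperative scene becomes invalid exactly when guidance matters most.
`apbnrr` implements **physics-based non-rigid registration (PBNRR)** and its
**adaptive extension (A-PBNRR)** that handles tumor resection, together with
the surrounding machinery: multi-tissue tetrahedral meshing from a
segmentation, block matching, registration-point-driven mesh adaptation,
Canny/Hausdorff and landmark evaluation, a synthetic phantom generator with
known ground truth, and a neural surrogate that ranks registration parameter
sets by predicted error.

It is aimed at medical-image-computing researchers who want a desk-scale,
fully testable re-implementation of this registration family: every stage
runs on synthetic phantoms in seconds to minutes on one CPU.

## The method

**PBNRR.** Feature blocks (size `B_s`, top fraction `F_s` by intensity
variance under a connectivity pattern) are selected in the preoperative
image and matched into the intraoperative image by exhaustive search over a
window `W_s`, maximizing normalized cross-correlation. The sparse matched
displacements `D` then drive a patient-specific linear-elastic finite-element
model (P1 tetrahedra; parenchyma E_b = 2.1 kPa, tumor E_t = 21 kPa,
ν = 0.45): the nodal displacement `U` solves

    U = argmin (HU − D)ᵀ S (HU − D) + λ UᵀKU,

where `H` interpolates nodal values at block centers, `S` carries the match
confidences, and `K` is the assembled stiffness. Outliers are rejected by
trimming the fraction `F_r` of blocks with the largest residual over `N_rej`
re-solves.

**A-PBNRR.** When tumor is resected, the preoperative model contains tissue
that no longer exists. The adaptive loop repeats: match → solve → locate
tumor elements that betray the cavity (blocks with no valid correspondence,
and/or elements whose displaced position samples near-background
intraoperative intensity) → excise them → re-tessellate — until the evidence
is exhausted or `N_iter_max` is reached.

**Evaluation.** Canny edge points of the preoperative image are pushed
through the computed field and compared against intraoperative edge points
by a percentile Hausdorff distance; paired anatomical landmarks give
min/max/mean errors. `summarize` builds the per-case HD table with
`HD_X / HD_A-PBNRR` ratios and column averages.

## Worked example

```python
import numpy as np
from apbnrr import (AdaptivePBNRR, PBNRR, PhantomSpec, RegistrationConfig,
                    make_case, case_hd)

spec = PhantomSpec(amplitude=5.0, eor=1.0, seed=2)   # total resection
preop, labels, intraop, truth = make_case("TR", spec)
config = RegistrationConfig().with_case_type("TR")

result = AdaptivePBNRR(intraop, preop, labels, config).fit()
print(result.summary())

mask = labels.brain_mask()
for name, field in [("identity", np.zeros(preop.shape + (3,))),
                    ("PBNRR", PBNRR(intraop, preop, labels, config).fit().dense_u),
                    ("A-PBNRR", result.dense_u)]:
    hd = case_hd(preop, intraop, field, mask, low=7, high=10, percentile=95)
    print(f"{name:9s} HD95 = {hd:.2f} mm")
```

prints (exact numbers vary with the seed):

```
Adaptive physics-based non-rigid registration (A-PBNRR)
========================================================
iterations: 2 (stop: zero-correspondence count 2 below threshold 5)
cumulative resected model volume: 6417 mm^3
  iter 0: 500 blocks, 13 zero-corr, 77 tets removed
  iter 1: 484 blocks, 2 zero-corr, 0 tets removed
max nodal displacement: 3.961 mm
identity  HD95 = 3.44 mm
PBNRR     HD95 = 2.94 mm
A-PBNRR   HD95 = 2.46 mm
```

The loop excised a model volume close to the true cavity (the phantom's
deformed tumor), and the edge-based error orders adaptive < plain <
unregistered — the behavior reported clinically for every resection case.

A command-line interface mirrors the library:

```bash
apbnrr phantom --eor 1.0 --amplitude 5 --seed 13 --out case/
apbnrr register --method apbnrr --fixed case/intraop.nii.gz \
    --moving case/preop.nii.gz --labels case/labels.nii.gz --out case/reg/
apbnrr evaluate --fixed case/intraop.nii.gz --moving case/preop.nii.gz \
    --field case/reg/field.nii.gz --landmarks case/landmarks.csv --out case/eval.json
```

## Layout

| module | contents |
|---|---|
| `apbnrr.core` | domain types, grid geometry, configuration |
| `apbnrr.io` | NIfTI/MetaImage, landmark CSV, VTK mesh, YAML config I/O |
| `apbnrr.phantom` | synthetic cases: textured brain, known deformation, resection |
| `apbnrr.mesher` | BCC-lattice multi-tissue tet meshing, quality/fidelity, removal |
| `apbnrr.blockmatch` | relevance, pattern-constrained selection, NCC matching |
| `apbnrr.fem` | elasticity assembly, approximation solve, outlier rejection, warping |
| `apbnrr.model` | `PBNRR` / `AdaptivePBNRR` model classes and results |
| `apbnrr.adaptation` | k-NN sizing, centered MVEE (Khachiyan), metric refinement |
| `apbnrr.evaluation` | 3D Canny, Hausdorff, landmark errors, summary tables |
| `apbnrr.surrogate` | 14-feature MLP HD predictor, run logging, ranking |

See `docs/methods.md` for the modeling choices, parameter semantics, and
known limitations.
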