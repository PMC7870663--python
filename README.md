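# innerear

Template, atlas and morphometry toolkit for the human inner ear (bony
labyrinth), exercised end to end on synthetic labyrinth phantoms with
analytic ground truth.

Building an in-vivo template and atlas of the labyrinth involves a chain of
image-analysis steps whose correctness is hard to audit on real MRI, where
no ground truth exists: reorientation to Reid's standard plane, ROI
cropping and left-ear mirroring, iterative unbiased template construction,
threshold-based surface extraction, registration-based transfer of atlas
annotations through signed-distance-transform (SDT) surrogates, a
landmark-based measurement protocol, and a battery of cohort statistics.
This package implements every one of those stages as a library, and pairs
them with a parametric phantom generator — torus-arc semicircular canals
with ampullae, an ellipsoidal vestibule with utricle and saccule, a
conical-spiral cochlea whose two scalae are separated by a thin dark gap in
a CISS-like channel — so that each stage, and the whole pipeline, can be
validated against known answers.  It is aimed at researchers in
computational neuro-otology and medical image analysis who need a testable
reference implementation of this pipeline.

## Core definitions

* Canal radius: `R = 0.5 · (height + width) / 2`, with height/width the
  outer bounding extents of the canal arc in its plane.
* In-ROI signal-to-noise ratio: `SNR = mean(I_ROI) / sd(I_ROI)`
  (population SD), the standard template-quality surrogate; averaging `n`
  aligned i.i.d.-noise volumes raises it ≈ `√n`.
* Signed distance transform: exact Euclidean distance between voxel
  centers, negative inside, so surfaces are zero level sets; registration
  minimizes the mean squared SDT difference in a ±2 mm band
  (rigid → affine → diffusion-regularized demons).
* Dice overlap: `2|A∩B| / (|A|+|B|)`; surface distances are signed
  point-to-triangle distances (negative = test inside reference) with
  min / max / mean / 5th / 95th percentile summaries.
* Cohort statistics: Lilliefors-corrected KS normality (Monte-Carlo
  p-values), paired t / rank tests with Benjamini-Hochberg FDR, Pearson
  correlation against total intracranial volume (TIV), and one-way ANCOVA
  `measure ~ sex + TIV` (Type-II sums of squares).

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

```python
from innerear.phantom import PhantomParams, generate_phantom, NOISE_SIGMA_SNR4
from innerear.surfaces import segment_bright_structure, extract_main_surface, mesh_volume
from innerear.morphometry import measure_all

params = PhantomParams(noise_sigma=NOISE_SIGMA_SNR4)   # SNR ~ 4
channels, truth = generate_phantom(params, seed=1)

report = measure_all(truth.landmarks)
print(round(report["scc_lat_radius"], 2))          # 2.9  (== parameter)
print(round(report["cochlea_length"], 2))          # 8.93 (truth 8.94)

thr, mask, smoothed = segment_bright_structure(channels["t2like"])
surface = extract_main_surface(smoothed, thr)
print(round(mesh_volume(surface), 1))              # 146.9 (truth 150.1 mm^3)
```

The lateral-canal radius comes back exactly at its generating value, the
contour-based cochlear length lands within 0.01 mm of the analytic truth,
and the Otsu-based iso-surface volume of the whole labyrinth is within
about 2% of the Monte-Carlo union volume of the generating primitives.

The numbered scripts under `analysis/` run the full study on phantom data:
cohort simulation, reorientation checks, template building, atlas label
transfer, morphometry tables with literature comparison, and the cohort
statistics battery.  Tables and figures land in `results/`; rendered
volumes (binary) land in `scratch/`.

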