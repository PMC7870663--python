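# Methods

This note documents the models and procedures implemented in `innerear`:
what the synthetic labyrinth phantoms emulate, how each pipeline stage is
defined, the numerical choices that matter, and what the phantom-based
checks do and do not demonstrate about real imaging data.

## The phantom model

The phantom is a parametric model of the bony labyrinth rendered into
multi-channel 3-D volumes, built from geometric primitives whose measures
are known in closed form:

* **Semicircular canals** — three torus arcs of 240° with circular lumen
  (radius `scc_lumen_radius`, default 0.65 mm) and hemispherical end caps.
  The canal "height" and "width" follow the visual convention of the
  measurement protocol: the outer bounding extents of the arc in its plane,
  height along the arc-apex direction (1.5 ρ + 2 r for centerline radius ρ),
  width across it (2 ρ + 2 r).  ρ is derived from the canal-radius parameter
  so that the conventional radius measure 0.25·(height + width) equals the
  parameter exactly (defaults 3.7 / 3.7 / 2.9 mm for the anterior /
  posterior / lateral canal).  The lateral canal lies in an axial plane; the
  anterior and posterior canal planes are vertical, at ±45° to the sagittal
  plane, so the three are mutually near-orthogonal.  The arc angle (240°)
  and the inter-canal angles are stated assumptions, exposed as module
  constants — the measurement literature gives no explicit values.
* **Common crus** — a capsule (cylinder with dome ends) of length 2.3 mm
  and width 2.1 mm joining the vertical canals to the vestibule.
* **Vestibule** — an ellipsoid with semi-axes (1.54, 2.695, 1.50) mm, so the
  maximal longitudinal/transverse diameters are 5.39 and 3.08 mm; utricle
  (ellipsoid, 8.9 mm³) and saccule (sphere, 2.6 mm³) sit inside it.
* **Cochlea** — a conical elliptical log-style spiral tube: centerline
  `c(t) = m₀ + A(t)·cos t·e₁ + B(t)·sin t·e₂ + z(t)·m` over
  `t ∈ [0, 2π·turns]` with 2.57 turns by default, linear radial taper
  (A shrinks to 25 % at the apex, B = 0.78 A), linear lumen taper (0.95 mm
  to 0.38 mm), and a tilted modiolar axis `m`.  The default base diameter
  (7.69 mm) and rise (3.06 mm) place the derived truth measures at
  cochlear length 8.94 mm, width 6.83 mm and oblique height 3.56 mm.
  A helical sheet of thickness `scala_gap` (default 0.45 mm) perpendicular
  to the modiolar direction splits the tube into scala vestibuli (superior)
  and scala tympani (inferior); where adjacent turns come within 0.3 mm of
  one another the space between them is treated as interscalar septum
  (bone).  A cochlear duct (thin tube riding the gap sheet near the outer
  wall) and an apical cupula dome complete the 13 atlas regions.
* **Connectivity bridges** — short tubes join each canal limb, ampulla and
  the basal cochlear turn to the vestibule, so the rendered labyrinth is a
  single connected bright structure (they are part of the rendered anatomy
  but not named atlas regions).

**Channels and noise.**  Three aligned channels are rendered on a
4 × 4 × 3 cm grid at 0.2 mm isotropic (defaults): `t2like` (fluid bright,
background 0.10 / tissue 1.00), `cisslike` (same, with the inter-scalae gap
and septum dark — the channel in which the scala separation is visible) and
`t1like` (low contrast, 0.35 / 0.58).  A Gaussian point-spread function
(FWHM 0.5 mm) and additive Gaussian noise complete the forward model.  The
default `noise_sigma = 0.29` puts the measured in-ROI SNR (mean/SD inside
the labyrinth mask) of the t2like channel at ≈ 2.5, the single-subject
regime of the reference SNR table; `NOISE_SIGMA_SNR4 = 0.135` gives
SNR ≈ 4, the level used for the recovery experiments.  These two constants
were calibrated once from the noiseless blur-texture floor (SNR ≈ 5.3) and
define the study conditions.

**Ground truth.**  Each phantom carries named landmarks for every endpoint
pair of the measurement protocol (≈ 200 points, including the four
Reid-plane head landmarks placed in the lateral-canal plane, the seven
equidistant basal-turn points, a 72-point basal-turn wall contour and the
modiolar/apex/round-window points), watertight region meshes, and a measure
table.  Distance truths are exact landmark-pair distances; composite
volumes (cochlea, whole labyrinth) come from a deterministic Monte-Carlo
integral over the union of primitives (fixed internal seed, sampled in
box-relative coordinates so the estimate scales exactly as s³ under
isotropic scaling).  A left-sided phantom is generated by reflecting the
geometry about the grid's mid-sagittal plane; because the voxel lattice is
symmetric about that plane, the noiseless left volume is the voxel-exact
mirror of its right twin, with identical truth measures.

**Cohorts.**  `generate_cohort` draws per-subject TIV from
N(1450, 120²) cm³ with a 100 cm³ male–female mean offset (field-typical
values), couples overall size to TIV through
`global_scale = 1 + 3·10⁻⁴·(TIV − 1450)`, and adds TIV-independent scale
noise (SD 0.02) plus per-ear noise (SD 0.01).  Without those two noise
terms the TIV–size correlation would be exactly 1 and paired side
differences identically zero, which would make the statistical battery
degenerate; with them, TIV explains most but not all size variation
(r ≈ 0.9 for total length) and side differences are small i.i.d.
perturbations.  `sex_effect` and `laterality_effect` multiply the scale
beyond TIV (both 0 by default — the null).  Cohort entries carry analytic
truth measures only; volumes render on demand.

## Pipeline stages

**Reid-plane alignment.**  `fit_reid_plane` is a total-least-squares plane
through the two infraorbital and two external-auditory-meatus landmarks
(smallest right singular vector of the centered coordinate matrix;
orientation-free by construction).  `reorient_to_plane` applies the
*smallest* rotation taking the plane normal to the superior axis — the
in-plane orientation is not constrained by a plane, and the
minimal-rotation convention is the documented choice.  Intensities are
interpolated with cubic B-splines.  `crop_roi` resamples the
40 × 40 × 30 mm box at 0.2 mm (200 × 200 × 150 voxels) and fills
out-of-volume voxels with the modal background intensity.
`mirror_sagittal` flips the first grid axis, an exact involution.

**Segmentation and surfaces.**  Otsu's threshold (256 bins, scikit-image)
degenerates when the structure occupies a fraction of a percent of the
histogram — the between-class criterion then prefers splitting the
background noise mode.  `segment_bright_structure` therefore (1) denoises
with a 0.8-voxel Gaussian, (2) runs Otsu restricted to the central 60 % box
of the grid, (3) re-runs Otsu over a 3-voxel shell around the rough mask,
where foreground and background are balanced and the threshold settles at
the edge midpoint, and (4) keeps the largest connected component.  Plain
Otsu at SNR 4 over-estimates the labyrinth volume by roughly 12 % (the same
magnitude as the overestimation reported for threshold-based iso-surfaces
of real templates); the balanced-shell refinement brings the volume error
to a few percent.  Iso-surfaces are marching cubes with linear edge
interpolation, vertices merged, mapped to world mm; surfaces whose level
set touches the grid boundary carry an `open` flag.  Mesh volumes use the
divergence theorem (absolute value, orientation-independent).  Voxelization
of closed meshes is a z-column parity rasterizer (voxel centers strictly
inside are set), with an irrational-ratio sub-voxel ray jitter so rays
never hit triangle edges through lattice points, and epsilon-slack
candidate bounding boxes.  The signed Euclidean distance transform is the
difference of two exact EDTs (distance to nearest opposite-class voxel
center; negative inside), so the surface is the zero level set.

**SDT label transfer.**  The atlas labyrinth surface and the subject
surface are voxelized and converted to SDTs, which act as surrogate images
for registration.  Both SDTs are truncated at ±2 mm: far from the surface
the distance values of two differently sized shapes disagree even under
the geometrically correct map, and the untruncated far field biases the
linear stage.  The rigid and affine stages are moments-initialized
(interior centroids; cube-root volume ratio for the initial scale) damped
least squares over a subsample of the fixed narrow band; the residual is
`SDT_moving(T(x)) − det(A)^⅓·SDT_fixed(x)` because an affine map that
scales space by s also scales distance values by s.  The deformable stage
is diffusion-regularized demons (update
`−(m−f)·∇m / (‖∇m‖² + (m−f)²)`, per-iteration step capped at half a voxel,
Gaussian field smoothing σ = 1 voxel, three resolution levels × 40–50
iterations), run on the affine-resampled, scale-normalized moving SDT.
Convergence is tracked as the mean |SDT mismatch| inside the |SDT| < 1 mm
narrow band (behaviour far from the surface is irrelevant).  The composed
map `T(x) = A(x + d(x))` carries atlas-space points into subject space;
meshes ride it by trilinear displacement interpolation at their vertices
(faces unchanged, closedness preserved).  Labelmaps are voxelized with an
explicit precedence order (ampullae > common crus > canals > duct/cupula >
scalae > saccule/utricle/vestibule) so thin structures are not swallowed.
The cochlear split thresholds the CISS-like channel inside the cochlea
mask, labels with 6-connectivity (the gap sheet is about one voxel thick;
diagonal connectivity would bridge it), takes two comparably sized seeds
from an eroded copy (partial-volume pinholes would otherwise merge the
scalae), assigns remaining bright voxels to the nearest seed, and applies a
1-voxel morphological closing as the automated stand-in for manual
clean-up.  The superior seed (world-z centroid) is labelled scala
vestibuli.

**Template construction.**  `build_template` iterates
register-every-subject-to-the-current-template → warp → voxelwise average →
recentre.  Per-subject alignment is multichannel phase-correlation
translation on z-scored channel composites (optionally refined by the
demons stage); the similarity is the unweighted per-channel sum, and
translation suffices because cohort crops share a canonical pose up to
residual offsets.  The template initializes from the first subject — a
voxelwise-mean start strands the registrations on a symmetric saddle when
subjects are symmetric about the mean — and the recentring step (subtract
the average translation) removes the first-subject bias, keeping the
template at the cohort barycenter (asserted: mean residual displacement
< 0.05 mm).  The convergence metric is the mean pairwise intensity MSE
across warped subjects (via the per-voxel variance identity), with the
unaligned stack as the baseline entry; after alignment it sits at the noise
floor.  Averaging n i.i.d.-noise volumes raises the in-ROI SNR ≈ √n until
the anatomical blur texture (which does not average away) becomes the
floor — this is why templates beat individual volumes and why the measured
gain trails √n at large n.

**Validation metrics.**  Dice is 2|A∩B|/(|A|+|B|) on a shared grid (both
masks empty raises — the value is undefined).  Signed surface distances
sample ≥ 10 points/mm² on the test surface; magnitudes are exact
point-to-triangle distances (candidates from a face-centroid KD-tree),
and the sign comes from the reference SDT (negative = test point inside
the reference).  Summary statistics are min, max, mean and the 5th/95th
linear-interpolation percentiles.

**Cohort statistics.**  Normality uses the Kolmogorov–Smirnov statistic
against a normal with estimated mean/SD (Lilliefors); p-values are
Monte-Carlo exceedance probabilities from a cached, internally seeded null
table of 10⁴ replicates per sample size — reproducible by construction and
slightly conservative.  Laterality testing gates the paired differences
through that normality test: paired two-tailed t where normal, otherwise —
deliberately reproducing the historical choice — the Mann-Whitney U test on
the two side samples, with the statistically conventional Wilcoxon
signed-rank available as `nonnormal_test="wilcoxon"`.  Family-wise
correction is Benjamini-Hochberg step-up (statsmodels).  TIV correlations
average the two sides within subject first (one value per subject), then
report Pearson r.  The sex comparison is a one-way ANCOVA
`measure ~ sex + TIV` with Type-II sums of squares (with a single factor
and covariate and no interaction, Type II and III coincide for the group
term); a zero-variance covariate reduces it exactly to one-way ANOVA.

## Problem sizes and experiment design

The end-to-end experiments run at desk scale: parameter recovery uses ten
phantoms at the production resolution (0.2 mm, SNR ≈ 4, random 3–8° tilts,
alternating sides, sizes in [0.93, 1.07]); label transfer registers a fixed
cohort-realistic phantom pair (scales 0.97 vs 1.04 plus small shape
differences) at 0.3 mm and scores at 0.2 mm; templates build from eight
subjects at 0.4 mm (≤ 128³ grids) with residual crop offsets up to
± 1.5 mm; the statistics calibration uses 100 null cohorts of 30 subjects
(plus 30 effect cohorts and 60 ANCOVA pairs).  The laterality type-I rate
is reported per decision (false rejections over all measure-level
decisions), which is the stable quantity; the fraction of wholly clean
seeds hovers at its nominal ≈ 95 % with binomial noise.

## What the phantom checks do and do not show

The phantoms share the real data's resolution regime, SNR regime, contrast
structure (including the CISS-only scala separation), left/right handling
and cohort covariate structure, so they exercise every pipeline contract
end to end against analytic ground truth.  They do **not** model bias
fields, air–bone susceptibility distortions, anatomical shape variability
beyond global scale and a few shape parameters, rater variability in
landmark placement (ground-truth landmarks replace the rater by design),
or the histology-level structures (organ of Corti, ampullary cupulae) that
the imaging cannot resolve anyway.  Passing the phantom battery therefore
validates the computational machinery and its calibration, not the
clinical accuracy of measurements on any particular scanner.

## Known limitations

* The canal region masks use analytic capsule/arc tests while meshes are
  swept polygons with dome caps; the two agree to well under a voxel but
  are not bit-identical representations.
* The demons stage is first-order and diffusion-regularized; it recovers
  cohort-scale shape differences but is not a diffeomorphic framework
  (the Jacobian fold check is reported, not enforced).
* Landmark-based measures inherit the exactness of the ground-truth
  landmarks; on real data the rater's placement error would dominate the
  sub-voxel arithmetic tested here.
* The interscalar-septum rule renders inter-turn contact as bone; a
  phantom with genuinely fused turns (gap → 0) is detected and rejected by
  the scala split rather than segmented.
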