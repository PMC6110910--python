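# Methods

## The measurement problem

Cerebral edema after hemispheric stroke displaces cerebrospinal fluid
before it shifts midline structures.  Serial CT therefore carries a
quantitative edema signal — the shrinking CSF compartment — long before
the conventional decompensation markers move.  The pipeline measures
that signal per scan (CSF ml, and as % of cranial volume), per subject
(maximal reduction = lowest volume as a percentage of the first-scan
baseline, floored at 0 if CSF rises), and per cohort (a marginal
longitudinal model).  Midline shift (mm at the septum pellucidum) and
the ordinal cerebral-edema grade (0–3; grade 3 = swelling with midline
shift) are radiologist readings and enter only as input covariates.

## Synthetic study system

No patient imaging ships with the package; every claim is validated on
a parametric phantom family whose ground truth is known exactly.

* **Geometry.** Concentric ellipsoidal skull shells (outer/inner
  semi-axes ≈ 82/74 × 84/76 × 62/55 mm) on a 64×64×26 grid at
  2.75×2.75×5 mm — head-CT-like anisotropy at desk-scale resolution.
  CSF = two ventricular ellipsoids (~18 ml) plus a sulcal shell: the
  0.90–0.98 radial band of the inner ellipsoid gated into ~14 angular
  wedges covering ~30% of the circumference (~80 ml, i.e. ~8% of a
  ~1300 ml cranial cavity).  An optional ellipsoidal infarct (~90 ml,
  matching a large cortical+subcortical lesion) can be placed in either
  hemisphere.
* **Contrast.** Air −1000, CSF 8, infarct 18, brain 32, skull 1000 HU,
  additive Gaussian noise with SD 4.  The 10 HU CSF–infarct separation
  at noise SD 4 is the deliberate confound: a fixed HU window cannot
  separate the two, a classifier with spatial context can.
* **Edema trajectory.** CSF retained fraction
  f(t) = floor + (1 − floor)·exp(−rate·t), the simplest monotone decay
  to an asymptote (defaults floor = 0.5 at rate 0.05/h, i.e. about half
  the baseline CSF lost by ~48–96 h).  Realized by eroding the CSF
  truth via the Euclidean distance transform (outermost voxels first,
  deterministic tie-break) with the vacated voxels refilled as brain, so
  cranial volume is conserved — the Monro–Kellie constraint the serial
  metric relies on.  Midline shift follows a compensation hinge:
  0 until the loss fraction exceeds a threshold (default 0.35), then
  30 mm per unit excess loss, chosen so a ~55% loss yields the ~6.5 mm
  shift typical of grade-3 edema.
* **Acquisition.** The DICOM writer emits single-frame CT
  (Explicit VR LE, rescale intercept −1100) with axial orientation
  cosines and per-slice positions advancing along the tilted slice
  normal, pivoting about the mid-stack isocenter: consecutive position
  tags are exactly the nominal gap apart while the in-plane origin
  drifts by z_gap·tanθ per slice.  Variable thickness is an explicit
  per-gap profile.  Deliberately wrong SliceThickness tags can be
  written to verify geometry is never read from them.
* **Cohort tables.** Within-subject residuals follow the stationary
  Gaussian recursion e_k = a^Δt·e_{k−1} + σ√(1−a^{2Δt})·z, whose
  correlation is exactly a^|Δt| at any gap pattern.  Defaults mirror
  cohort-scale values: coefficients (1500, −22, +0.3, 3.01, −32.57) in
  ml, a = 0.6/day, σ = 20 ml, ages N(67, 14²), 32% grade-3 prevalence,
  2–5 scans in a 5-day window.

What the phantoms do **not** emulate: real tissue texture, partial
volume at acquisition (compartments are piecewise constant), beam
hardening and streak artifacts, hemorrhage, and anatomical variability
beyond affine-scale shape changes.  Passing tests therefore demonstrate
correctness of the algorithms under controlled contrast and geometry,
not clinical-grade accuracy on patient scans.

## Numerical and design choices

* **Ingestion.** Slice gaps are Euclidean distances between consecutive
  position tags (tolerance 0.01 mm for uniformity); the tilt angle is
  the arctangent of in-plane drift over normal advance.  Tilt
  correction shifts each slice by −drift/pixel-spacing with linear
  interpolation, aligned to the mid-stack frame (the isocenter frame
  clips the least anatomy; the resulting in-plane origin offset is kept
  in the NIfTI affine).  Variable gaps are resampled to the **minimum**
  gap (up-sampling; thin posterior-fossa slices keep their detail) with
  linear interpolation; an already-uniform untilted series passes
  through bit-identically.  Series selection drops derived images,
  bone kernels, non-axial stacks and a configurable description lexicon
  (descriptions vary by site and language), then prefers the most
  slices, tie-broken by earliest acquisition time.
* **Skull strip.** k = 3 (air/external, soft tissue, bone); scalar
  k-means equals optimal midpoint thresholding in 1-D, which the tests
  exploit as an oracle.  Morphology: slice-wise then 3-D hole filling
  (re-capturing CSF, which lies below the soft-tissue center), removal
  of voxels border-connected through non-bone paths (6-connectivity,
  conservative against thin skull gaps), then the largest
  26-component.
* **Registration.** Rigid/affine only — intra-subject CT alignment and
  perimeter delineation do not need a deformable stage at phantom
  scale.  A 3-level (shrink 4/2/1) regular-step gradient descent on
  normalized cross-correlation seeds a full-resolution Powell
  refinement of the six rigid parameters; the metric is evaluated on
  the in-FOV overlap only (constant padding must not masquerade as
  structure), and an |NCC| below 0.3 — or overlap below 25% — raises a
  registration failure instead of returning silently.  The affine stage
  keeps whichever of its result or the rigid seed scores better under
  the same evaluator.  Masks are always resampled nearest-neighbor
  (linear interpolation biases binary volumes).  Atlas fusion uses a
  strict majority (> N/2) with the threshold recomputed on surviving
  templates when registrations are dropped; the propagation QC flags a
  follow-up when the propagated cranial volume deviates more than 10%
  from baseline (the failure criterion itself is this package's
  convention).
* **CSF classifier.** Feature bank per scale s ∈ {1, 2, 4, 8} voxels:
  center box mean, center−surround difference, and left−right /
  up−down / front−back paired non-overlapping box differences, plus raw
  HU and 3×3×1 local mean/SD — 23 features, all from one summed-area
  table (plus one of squares), boxes clipped at bounds and renormalized
  by actual voxel count.  Boxes are 2-D in-plane by default because
  slices are ~2× thicker than in-plane pixels (3-D via
  ``use_3d``).  Forest: 100 trees, depth ≤ 20, √d features per split,
  balanced sampling capped at 4000 voxels per class per volume,
  out-of-bag accuracy recorded in the bundle provenance.  Probability
  cutoff 0.5, configurable.
* **Active contour.** Morphological Chan–Vese, two-phase, run
  slice-wise (3-D curvature operators erode fluid sheets one slice
  thick) with non-cranial voxels filled at the brain-tissue median so
  they act as background.  On piecewise-constant phantoms the forest
  already localizes the boundary at voxel precision and the global
  two-phase model absorbs infarct-intensity tissue into the fluid
  phase, so the pipeline applies refinement only when
  ``refine_iterations > 0`` (default 0); the operation is exercised and
  tested on the contracts it is designed for (fixed point on two-region
  images, contraction from a dilated initialization, perimeter
  monotonicity under heavy smoothing).
* **GEE.** Time is modeled in days (hours accepted at the interface).
  Two-stage iteration: GLS update of b given (a, σ²); σ² by moments
  with denominator N − 5; a by least squares of a^Δt on within-subject
  Pearson-residual cross-products, minimized on a 50-point log-spaced
  grid over (10⁻⁶, 1−10⁻⁶) refined by bounded scalar search.
  Convergence when max|Δb| < 10⁻⁶·(1+|b|); near-singular working
  correlations (a → 1, near-duplicate times) get a 10⁻⁸ diagonal
  ridge.  With no within-subject pairs the fit is exactly OLS and a is
  reported as undefined.  Inference: sandwich covariance
  B⁻¹MB⁻¹ with normal-reference Wald p-values and no small-sample
  correction.  The response is absolute ml; percent-of-baseline can be
  fit by passing that column as the response.
* **Midline-shift model.** OLS quadratic of peak shift on maximal
  reduction, F-test of the quadratic term against the nested linear
  model, pointwise 95% mean-response band.  The decompensation onset is
  read where the **rising branch** (beyond the parabola's vertex) first
  exceeds 1 mm — the left branch above the vertex is an artifact of
  fitting a parabola to a hinge and is ignored.
* **Cohort rules.** Subjects need ≥ 2 scans; a subject whose only
  follow-up is beyond 168 h is excluded; QC-flagged scans are dropped
  first; every exclusion is logged with a reason (no silent drops).
  Duplicate (subject, time) pairs are an error.  "Baseline" for the
  reduction metric is the first scan, per the metric's definition.
  Overlays are lossless PNG (windowed to center 40 / width 80 HU) and
  byte-reproducible.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as this
package's study conditions: default phantoms of 64×64×26 voxels; the
rigid-recovery study uses 20 jitters (tests) / 12 (script); mask
propagation cohorts of 24 / 16 subjects with one follow-up each;
segmentation with 10 train / 5 test phantoms (script: 6 / 3); GEE
recovery at n = 300 subjects × 100 replicates (script: 30); the
cross-sectional models at n = 100–150.

## Known limitations

* Geometry is ellipsoidal and piecewise constant; segmentation scores
  on phantoms are optimistic relative to patient CT.
* Rigid motion between scans is simulated with linear interpolation,
  which blurs one-voxel-thick sulcal CSF; pipeline volumetrics on
  jittered series slightly overestimate CSF loss for that reason.
* The multi-atlas stage encodes posterior-fossa exclusion only through
  what the template masks contain; no separate parcellation exists.
* The classifier is trained on synthetic contrast and is not a
  substitute for a cohort-trained model; the bundle format (forest +
  feature spec + provenance) is the intended transfer mechanism.
* Midline shift and edema grade are never computed from images.
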