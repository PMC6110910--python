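# edemascan

Quantifying cerebral edema after ischemic stroke as the serial reduction
of cerebrospinal fluid (CSF) volume on routine head CT.

After a hemispheric infarct, swelling first displaces CSF from the
ventricles, sulci and cisterns before midline structures shift; the CSF
volume trajectory is therefore a sensitive, continuously measurable
marker of edema progression, available from every clinical CT.
`edemascan` implements the automated pipeline that turns raw serial
DICOM series into that trajectory and models it across a cohort:

1. **Ingestion** — slice spacing computed from position tags (never from
   thickness tags), gantry-tilt shear correction by trigonometric
   resampling, interpolation of variable slice thickness to a uniform
   grid, NIfTI + BIDS-style sidecar output.
2. **Skull stripping** — k-means clustering of HU into external/soft
   tissue/bone, plus morphology (hole filling, border suppression,
   largest component) to isolate the intracranial contents.
3. **Cranial perimeter** — multi-atlas majority vote: template masks are
   registered onto the baseline and a voxel is kept iff it matches in
   strictly more than half of the templates; the baseline mask is then
   propagated to each follow-up by rigid registration, with a
   cranial-volume-ratio QC rule flagging failures.
4. **CSF segmentation** — a random-forest voxel classifier on Haar-like
   box features (computed in O(1) per box from a 3-D summed-area table),
   optional morphological Chan–Vese refinement, and cleaning with the
   manually outlined infarct mask.  A plain HU-window baseline is
   provided because infarct density mimics CSF and confounds it.
5. **Volumetrics** — masks to ml via the voxel geometry; the headline
   metric is the maximal reduction, the lowest measured CSF volume as a
   percentage of the baseline volume.
6. **Longitudinal model** — GEE with identity link,

   E(y_ij) = b0 + b1·t_ij + b2·t_ij² + b3·age_i + b4·ced_i,

   under the continuous-time Markov working correlation
   corr(y_ij, y_ik) = a^|t_ij − t_ik| (0 < a < 1), estimated by a
   two-stage iteration (GLS for b; moments for σ²; least squares on
   residual cross-products for a) with robust sandwich covariance.
   Cross-sectional companions: the quadratic model of peak midline shift
   against maximal CSF loss, and the regression of baseline CSF fraction
   on age.

Real stroke cohorts are not redistributable, so the package ships a
first-class synthetic module (`edemascan.phantom`): parametric head
phantoms with exact ground-truth masks, simulated tilted/variable-
thickness DICOM acquisitions, longitudinal edema series obeying the
Monro–Kellie constraint (CSF contracts, cranial volume is conserved),
and cohort-level CSF tables with exactly the Markov correlation
structure.  Every stage is validated against that ground truth.

## Worked example

`examples/04_gee_dynamic_model.py` simulates 300 subjects (2–5 scans
each over five days, irregular gaps) and refits the dynamic CSF model:

```
        coef    estimate  robust_se          z            p
   intercept 1492.209849   3.817884 390.847352 0.000000e+00
   time_days  -22.552992   1.080204 -20.878448 8.407883e-97
time_days_sq    0.463864   0.238403   1.945711 5.168943e-02
   age_years    3.104294   0.053622  57.892431 0.000000e+00
        ced3  -31.718013   1.750120 -18.123333 2.085678e-73
working correlation a = 0.632 per day (truth 0.6), residual SD = 20.0 ml (truth 20.0)
```

Read: CSF falls ≈22.6 ml per day early after stroke (decelerating via
the positive quadratic term), is ≈3.1 ml higher per year of age
(atrophy), and ≈32 ml lower in subjects with edema grade 3 (swelling
with midline shift); within-subject correlation decays to 0.63 per day
of gap.  Each estimate sits within ~2 robust SEs of the simulator's
generating coefficients (1500, −22, +0.3, 3.01, −32.57, a = 0.6).

The other examples cover tilted-DICOM round trips (`01`), skull
stripping and forest-vs-threshold segmentation (`02`), longitudinal
registration and maximal reduction (`03`), and the midline-shift /
age models (`05`); each prints the numbers it computes and what they
mean.

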