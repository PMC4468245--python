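# Methods

`pibgm` implements a fully automatic analysis chain for co-registered
whole-body PET/CT aimed at quantifying bone glucose metabolism, with a
diagnostic application to fever of unknown origin (FUO).  This note records
the models, the numerical choices, and what the synthetic test bed does and
does not establish.

## Pipeline overview

CT supplies anatomy (Hounsfield units), PET supplies function (activity
concentration, Bq/mL); the scanner acquires them co-registered.  The chain
is: PET upsampling onto the CT grid → bed removal → histogram
auto-thresholding → active-contour bone segmentation → cortex/marrow
labeling → SUV conversion → PIBGM → cohort diagnostics.

### PET upsampling

Clinical grids differ (CT 512², PET 168²).  The default scheme replicates
each PET pixel into a 3×3 block (168 → 504) and pads all four sides with an
equal zero border to reach the CT size; in-plane spacing is divided by 3 and
the origin shifted so voxel centres stay fixed in world space.  Replication
preserves values exactly (sum scales by exactly 9) and is invertible by
block mode, so downstream SUV statistics are unaffected by the resampling.
A trilinear interpolant is provided as an alternative
(`upsample_pet_trilinear`) for users who prefer a smooth field; it is exact
on constants and linear ramps.  Replication is the default because it is the
procedure the pipeline's other stages are calibrated against; the two differ
only in how boundary voxels share values.

### Bed removal

The scanner bed absorbs X-rays but emits no positrons, so it appears in CT
and never in PET.  The body outline is therefore taken from PET: Gaussian
smoothing (default σ = 2 voxels), a threshold (default 1 % of the smoothed
maximum; Otsu optional), largest connected component, hole filling.  CT
voxels outside the outline are replaced by −1000 HU (air), *not* multiplied
by zero: 0 HU is water, and a large zero-filled background would plant a
spurious soft-tissue mode in the intensity histogram the next stage fits.

Smoothing dilates a thresholded outline by roughly σ·Φ⁻¹(boundary/threshold)
voxels.  On clinical 512² grids this is negligible relative to the body;
on the small phantom grids used in tests it is not, which is why exactness
tests run with σ = 0 and why the segmentation stage re-restricts its domain
by HU (below).  A generous body mask is harmless downstream; a truncated one
is not.

### Histogram auto-thresholding

The HU histogram of the body-masked CT is modelled as two Gaussians
`y(x) = A_m exp(−((x−B_m)/c_m)²) + A_f exp(−((x−B_f)/c_f)²)` for muscle and
fat; bone occupies too small a volume fraction to form its own resolvable
mode.  The fit is nonlinear least squares on the binned counts (default 128
bins over −200…300 HU, a window that excludes air and dense cortical bone,
which the two-component model does not describe).  Initialization: the two
tallest histogram peaks at least 50 HU apart; widths start at half the peak
separation; centres are bounded to the window; widths are floored at half a
bin (narrower is unresolvable, and the floor keeps the optimizer off a slow
boundary path on noise-free spike histograms).  Failure modes (flat or
unimodal histograms, non-convergence) raise explicit errors carrying the
last iterate.

The bone pre-segmentation threshold is
`T = B_m + (ω/2)(B_m − B_f)` — a point above the muscle centre by a
fraction of the fat–muscle separation.  ω defaults to 0.5, which on the
default tissue model (fat −100, muscle 40) gives T ≈ 75 HU, comfortably
between muscle and marrow (150 HU).  ω is exposed because the right margin
depends on scanner noise.

### Bone segmentation (threshold-augmented Chan–Vese)

The pre-segmented mask is refined slice-wise in 2D by a two-phase
region-competition energy

    F(C) = Σ_inside [(I−c1)² + ε(I−Th)²] + Σ_outside [(I−c2)² + ε(I−Th)²]

with c1, c2 the region means, Th the pre-segmentation threshold and ε a
weighting coefficient (default 1).  As written the ε term covers the whole
domain, so it contributes a constant offset: `cv_energy` evaluates the
literal sum, while the evolution force is the difference of the two
integrands, in which the ε parts cancel.  Smoothness enters through an
optional contour-length term with weight μ (default 0.1 × dynamic-range²,
commensurate with the squared-intensity data forces); μ = 0 reproduces the
bare energy.

Two numerical regimes:

* **μ = 0 (exact).**  The energy depends only on which intensities go to
  which region.  Alternating mean/assignment sweeps (each monotonically
  non-increasing in energy) are followed by an exact scan over
  value-threshold partitions; the global optimum of a two-mean
  sum-of-squares split of scalars is always such a partition, so the scan
  attains it.  Tests verify this against exhaustive enumeration of all
  labelings on images up to 4×4.
* **μ > 0 (level set).**  Signed-distance initialization from the
  pre-segmentation, compact-support smoothed delta of width ≈ 1.5 voxels,
  curvature term, re-initialization every 10 iterations, CFL-style step
  normalization (max update 0.45 per iteration), stop after three
  consecutive iterations in which fewer than a `tol` fraction (default
  10⁻⁴) of voxels change sign, cap at 200 iterations.  The compact delta
  freezes voxels away from the contour — this is what lets the marrow core,
  whose HU resembles soft tissue, survive inside its cortical shell while
  isolated false positives in muscle are eroded away.

The competition domain is the body mask further restricted to voxels above
−500 HU.  Without this, residual air inside a generous body outline drags
the outside mean toward −1000 HU and the global optimum becomes
body-versus-air rather than bone-versus-soft-tissue.

Evolution is 2D per slice (stacked into the volume); segmentation quality is
scored per volume by TPR, FPR and Dice against ground truth.  Bone voxels
are then labelled cortex or marrow by an intensity split — Otsu over the
within-bone HU distribution by default, or a fixed HU cutoff
(`fixed:<HU>`) — and the labels transfer per-voxel onto the co-registered
PET.

### SUV

SUV divides tissue concentration (MBq/mL) by injected dose per unit of a
body-size normalizer: body weight (`bw`), body surface area (`bsa`, DuBois:
0.007184·w^0.425·h^0.725), or lean body mass (`lbm`, James: 1.07w−148(w/h)²
female, 1.1w−120(w/h)² male).  `bsa()` and `lbm()` return m² and kg; inside
`suv_map` the mass normalizers are taken in grams and BSA in cm², which
places the three SUV flavours on the magnitudes clinical cohorts report
(SUV_lbm ≈ 0.7–0.8 × SUV_bw; SUV_bsa ≈ 0.26 × SUV_bw).  PET values are
assumed decay-corrected by the scanner; no further decay correction is
applied.  All three maps are linear in activity and inversely linear in
dose, and the tests pin the unit conversions.

### PIBGM

The PET Index of Bone Glucose Metabolism at SUV cutoff t is the fraction of
bone-region voxels whose SUV strictly exceeds t: `PIBGM(t) = N_t / N_b`.
Ties at exactly t do not count.  It is computed per region (whole bone,
cortex, marrow) over a cutoff grid, default 0.4 to 2.2 in steps of 0.2, and
is non-increasing in t by construction.  PIBGM generalizes the planar bone
scan index to volumetric PET: it measures *how much* of the skeleton is
metabolically hot rather than *how hot* its mean is, which is what makes it
robust to diffuse, patchy uptake patterns.

### Diagnostics

Classification is one-sided on a scalar biomarker: abnormal iff strictly
greater than a cutoff.  Cutoffs come from the DANP rule (Discriminative
Ability for the Normal Person): with target d and n normal subjects, the
cutoff is the ⌈d·n⌉-th order statistic of the normal values, so the
specificity on the defining set is at least d, and exactly ⌈d·n⌉/n when the
values are distinct — at every SUV cutoff t simultaneously, which is why
specificity is flat across the sweep.  No interpolation between order
statistics is used: the "fraction of normals identified" semantics is then
met exactly.  The default decision biomarker is cortex PIBGM at t = 1.2
(the sweep's peak operating point); both region and t are configurable.

Group comparisons use Welch's unequal-variance t-test (two-sided).  Raw
p-values are reported; no multiplicity correction is applied across the t
grid, and they are labelled as raw.  ROC curves use every score threshold;
AUC is trapezoidal (equal to tie-corrected pairwise concordance) and graded
qualitatively: ≥0.9 Excellent, 0.8–0.9 Good, 0.7–0.8 Worthless, 0.6–0.7
Not good, below 0.6 Fail.  The band names are kept exactly as the grading
table this package follows prints them, surprising ordering included.
Evaluation is in-sample; cross-validation is out of scope.

## The phantom

The phantom is a stylized torso, not an anatomy: stacked identical ellipses
forming fat ⊃ muscle ⊃ cortex ⊃ marrow cylinders in air, with an optional
bed arc (elliptical annulus segment, 300 HU) below the body.  Defaults: grid
16×64×64 at 5×4×4 mm, HU means fat −100 / muscle 40 / marrow 150 / cortex
700 (air −1000), per-tissue HU noise (15–30 HU), PET uptake set so each
tissue's voxel SUV_bw equals a prescribed baseline (fat 0.3, muscle 0.5,
marrow 0.93, cortex 0.86 — marrow hotter than cortex, soft tissue well
below bone) given the patient metadata, plus optional in-body PET noise and
compact focal lesions.  Cohorts add group-level cortex uplifts (default
+0.20/+0.17/+0.23 SUV for inflammatory/infection/neoplasm over normal,
the normal-vs-FUO ordering) and a per-patient random uptake effect
(SD 0.12 SUV).  All randomness flows from one seeded generator; identical
spec + seed is byte-identical.

A second, cheaper generator (`make_profile_cohort`) skips imaging entirely
and draws per-patient PIBGM *profiles* as survival functions of lognormal
SUV distributions — continuous, hence distinct across patients almost
surely — for exercising the cohort statistics at scale.

What the phantom does not emulate: anatomical shape, scanner physics
(scatter, attenuation, reconstruction artifacts, partial-volume blur),
intra-tissue HU gradients, and lesion morphology.  Passing tests therefore
establish the *algorithmic* properties (exact recovery under the intensity
model, graceful degradation under additive noise, unit correctness,
by-construction statistical behaviour) — not clinical segmentation accuracy
on real patients, which depends on precisely the effects the phantom leaves
out.

## Problem sizes and determinism

Tests run on 16×64×64 phantoms (≈65k voxels), cohorts of 8–30 synthetic
patients for the imaging path and 160 patients for the profile path, 10⁶
draws per histogram-recovery replicate, and exhaustive enumeration up to
4×4 images (≈65k labelings) for the energy oracle; these sizes make every
property checkable at full precision while keeping the suite fast.  The
whole chain is deterministic given config + seed: reports embed a config
hash and version, and re-running reproduces numerical content bit-for-bit
(timestamps excluded).

## Known limitations

* 2D slice-wise evolution: no through-plane smoothness; a 3D mode is out of
  scope.
* The two-Gaussian model fails (by design, with an explicit error) on
  histograms without two separated soft-tissue modes — e.g. limbs-only
  fields of view.
* The μ > 0 level set is a local optimizer; quality depends on the
  pre-segmentation being roughly right, which the threshold stage provides.
* BSA/LBM formulas are adult formulas; the LBM quadratic goes negative for
  extreme weight/height ratios and is rejected rather than clamped.
* DANP cutoffs are in-sample order statistics; generalization error of the
  operating point is not estimated.
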