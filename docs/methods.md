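# Methods

This note documents the models and numerical conventions behind
`rvatlas`: what the synthetic cohort emulates, how each pipeline stage
works, which choices were genuinely open, and what the tests do and do
not demonstrate about clinical data.

## Synthetic anatomy

The ventricle is an idealized **crescent-section half-ellipsoid**. Each
surface (endocardium, epicardium) is a grid of 24 rings × 24
circumferential vertices; ring radius follows an ellipsoidal
base-to-apex profile and the cross-section is a limaçon
r(φ) = R·(1 − c·cos φ) with c = 0.55, whose inward dimple at φ = 0
plays the role of the septum. The template measures 50 mm base-to-apex
with a 22 mm epicardial base radius and a 4 mm nominal wall. Two closed
triangulated surfaces of 576 vertices each give the fixed 1152-vertex /
**3456-entry shape vector** parameterization (vertices × 3 coordinates;
endo block first, x,y,z per vertex). The idealization buys exactness:
volume, caliper diameter, wall thickness and cross-section geometry are
all analytically checkable, which is what makes the acceptance suite
possible. An LV-landmark anchor point sits just septal of the base ring
and is rasterized as a small label-3 disc on the most basal slice.

Per-subject deformation applies, in this fixed order: wall-thickness
rescaling of the matched endo→epi gap → uniform dilation (cavity volume
scales with the cube) → long-axis stretch (the sphericity control) →
base widening with a linear taper to the apex → apex-tilt shear →
i.i.d. vertex noise along surface normals. Noise is texture, not
topology: matched wall thickness is clamped at 0.3 mm so random
perturbations can never cross the surfaces, while parameter
combinations that *deterministically* collapse the wall are rejected
with a diagnostic. The septal wall is thinner than the free wall by
the limaçon factor (≈0.45×), so the "wall thickness" parameter is the
nominal free-profile value, not a spatial constant.

## Synthetic motion and cine

Cine motion is an affine contraction diag(c(t), c(t), l(t)) of the
end-diastolic mesh, driven by a smooth sin²/cos² activation that rises
from 0 at end-diastole to 1 at end-systole (default systole fraction
0.4 of a 0.5 s RR interval, 25 frames). c(t) realizes the prescribed
peak circumferential strain exactly (a closed contour's perimeter
scales by c); l(t) is solved with Brent's method so the four-chamber
polyline shortens by the prescribed peak longitudinal strain at
end-systole. With the incompressible-wall flag the epicardial in-plane
scale e(t) is solved in closed form per frame so that shell volume
e²l·V_epi − c²l·V_endo stays at its end-diastolic value.

Tracked contours are material points: the frame-0 contours (three
short-axis levels at 25/50/75% of the long-axis extent, plus a
four-chamber polyline through the septum–free-wall plane) are
transported by the per-frame affine map. Ground-truth strain curves
are computed *from the generated contours themselves*, so truth and
data agree to machine precision by construction, and the recorded EF
satisfies (EDV−ESV)/EDV × 100 on the analytic volume curve c²l·V₀.

A deliberate consequence of this simple motion model: peak strains in
the physiologic feature-tracking range (circumferential ≈ −15%,
longitudinal ≈ −14%) imply c²l ≈ 0.62, i.e. EF ≈ 35–40%, lower than
the ≈57% such patients show clinically. Real ventricles achieve higher
EF through regional heterogeneity and basal descent that a global
affine map cannot represent. The generator treats the *strain targets*
as primary; every EF check in the pipeline is a self-consistency check
(measured vs. analytic EF of the same motion), so nothing downstream
depends on clinical EF magnitudes.

## Cohorts

`default_cohort_config()` builds the study-like population: four arms
(MBT/RVPA × stage I/II) of 30/20/29/14 subjects, stage-specific BSA
distributions (0.40±0.04 / 0.44±0.06 / 0.67±0.17 / 0.70±0.11 m²),
arm-specific indexed-EDV levels (83/110/77/98 ml/BSA^1.3) and
sphericity targets (1.47/1.41/1.52/1.24). Dilation is *solved* per
subject so that end-diastolic cavity volume equals the drawn indexed
EDV × BSA^1.3 — cohorts are allometrically consistent by construction.
Heights are drawn per stage and weights back-computed through the
Haycock formula, so the metadata is internally consistent too.
TR fractions and LV-shape categories are sampled metadata only.

Seeding: per-subject streams come from `SeedSequence([seed, arm_index,
subject_index])`, so resizing one arm never reshuffles another —
cohort tables are reproducible byte-for-byte under a fixed seed.

The two-group experiment config (`two_group_config`) injects a single
effect on log indexed EDV at a chosen standardized effect size d. Its
nuisance spreads (sphericity SD 0.04, base-width SD 0.04, tilt SD 2°,
noise 0.3 mm, dilation log-SD 0.25) are chosen so dilation is a
*separable* factor of shape variation: a uniform-scale displacement
direction overlaps strongly with the long-axis-stretch direction in
shape space, and if their variances are comparable PCA mixes them into
hybrid modes, defeating single-mode recovery regardless of sample
size. With these spreads the dilation mode is recovered as exactly one
Bonferroni-significant mode whose scores correlate |r| > 0.9 with the
generative dilation in ≳95% of replicates at d = 1.2, n = 40/arm.

## Mesh personalization

1. **Loading** normalizes slice order so the landmark slice is index 0
   (flipping apex-to-base stacks), and enforces the label contract
   (missing RV labels, missing landmark, landmark on several slices are
   distinct errors).
2. **Boundary extraction** traces per-slice contours of the cavity and
   of cavity+myocardium at the half-voxel iso-level and resamples each
   to 40 points by arc length. Effective slice spacing is thickness
   plus gap.
3. **Pose standardization** is rigid only — rotation plus translation,
   never scaling, because ventricular size is a finding. The long axis
   is the line fitted through per-slice contour centroids, mapped to
   +z (base at the origin); the in-plane direction to the LV landmark
   fixes +x. Because the computation uses only the points and their
   slice grouping, it is rigidly equivariant, hence idempotent.
4. **Template fitting** works in the template's native frame (reached
   from the standardized frame by the template's own pose under the
   same rule — this fixed frame is the common atlas frame). Each
   surface is fitted by *template-relative radial kernel regression*:
   every boundary point's radius about the long axis is expressed as a
   ratio to the template radius at the same normalized height and
   angle, the ratio field is kernel-regressed onto the vertex grid
   with a coarse-to-fine bandwidth schedule, and an update is accepted
   only if the mean point-to-surface distance decreases — so the
   per-iteration error log is monotone by construction, and
   `fitting_error_mm` is the final mean point-to-surface distance over
   all boundary points. The template profile acts as the prior
   wherever slices carry no data (between slice planes, at the apex).

   A free-form alternative (nearest-vertex correspondence with a
   Laplacian-smoothed displacement warp) was implemented first and
   rejected: with boundary data confined to ~10 slice planes it
   overfits between planes and biases cavity volume by 5–6%, and its
   smoothing flattens the septal dimple. The kernel fit reaches
   ~0.2–0.4 mm mean error (sub-voxel at 1.5 mm) with <1–3% volume
   error on noiseless stacks.

   Exact point-to-triangle distances are computed in-package (KD-tree
   candidate faces with a provable distance bound, then exact
   point–triangle tests).

Known quantization limits: the apex is only supported to ±half a slice
(whether a marginal apex section is rasterized can depend on grid
alignment), so fitted apex coordinates carry that uncertainty — the
same limit manual contouring of real stacks has.

## Geometry and indexing

ED and ES are the volume-curve extremes, not fixed frame indices.
Simpson volumetry sums area × effective spacing. Myocardial mass uses
1.05 g/ml (standard density). The sphericity ratio is defined as
base-to-apex length ÷ maximum cavity caliper diameter — chosen because
the study-style cohort tables are consistent with that reading (length
≈ 77.8 / diameter ≈ 53.0 ≈ 1.47 vs. a printed mean of 1.49, a
mean-of-ratios vs. ratio-of-means gap) and not with the epicardial
diameter. Wall thickness is the matched endo→epi vertex distance; the
septal SD is taken over the septal vertex mask. Allometric indexing
divides volumes by BSA^1.3 and lengths by √BSA; the exponent for mass
is ambiguous in the field's own tables (printed both ways), so it is a
configuration option defaulting to 1.3, recorded in output metadata.
TR grading bins are <15% mild, 15–25% moderate, 25–45%
moderate–severe, >45% severe, with boundary values assigned to the
lower-severity bin and exactly 0 reported as none.

## Shape atlas

PCA is computed on raw mm coordinates of the pooled cohort (no
per-feature standardization: units are homogeneous and size is
signal), via SVD of the centred data matrix; eigenvalues are
cross-checked in the tests against a brute-force covariance
eigendecomposition. Mode signs are fixed by making the
largest-magnitude loading positive. `explained_variance` uses the full
spectrum, so truncation to K = 10 modes never distorts the
denominator. Reconstruction along mode m at k SDs uses score
k·√λ_m. Mode comparison runs per-mode one-way ANOVA across groups
with Bonferroni adjustment over the K tested modes (capped at 1);
exact-tie degeneracies (a zero-variance group) fall back to a seeded
10 000-permutation test. Stage-stratified comparisons reuse the pooled
modes, matching the single-atlas design. Modes are reported by
eigen-rank only; no claim is made that a given rank corresponds to any
particular published mode number.

## Strain

The commercial feature tracker is proprietary; the package substitutes
boundary extraction + arc-length re-parameterization + cyclic
minimal-shift matching, transported as a displacement field applied to
the user's initial contour (so rigid cine motion is exactly
strain-free — extraction bias cancels between frames). This is valid
on label-based synthetic cines and is stated as a simplification.
Six segments per level by default (the field's segment counts vary and
are rarely stated). Circumferential/longitudinal strain is Lagrangian
on segment arc lengths vs. frame 0 (= end-diastole by generator
guarantee); radial strain is thickness-based when epicardial contours
exist, otherwise inverted centroid-distance change so physiologic
inward motion is positive; both variants are labelled in the output.
Strain rate is the central finite difference of the strain *fraction*
over the frame interval (s⁻¹). The systolic peak is the
largest-magnitude value in [ED, ES]; the diastolic peak is the single
largest-magnitude rate in (ES, cycle end] — early vs. late diastole
are not distinguished, and this is flagged in the result rather than
guessed. Short-axis level selection takes the slices nearest 25/50/75%
of the base→apex extent.

## Statistics

Continuous two-group comparisons use the equal-variance Student t-test
(the plain "unpaired t-test"; Welch is available as a switch and the
choice is recorded). Shapiro–Wilk normality is reported per group but
never auto-switches the test. χ² is Pearson without continuity
correction, with expected-count warnings. ICC is ICC(A,1) — two-way
random effects, absolute agreement, single rater — computed from the
mean-squares decomposition with the McGraw–Wong F-based 95% CI, and
cross-checked against pingouin in the tests. Report tables mirror the
four-table study layout (demographics; indexed volumes/EF in Total /
stage I / stage II blocks; 2D geometric indices; strain peaks by
direction and level) with mean ± SD, p-values and a p < 0.05
significance flag.

## Problem sizes and what the tests show

The validation studies run at the sizes the properties are stated at:
200 replicate cohorts of 40/arm for dilation-mode recovery, 500
replicate null cohorts of 20/arm for family-wise error, 93 subjects
for the study-sized atlas, 1 mm voxels for analytic-solid volumetry.
Replicate experiments draw shape vectors directly from the generator
(deformed template meshes) rather than re-fitting 30 000+
segmentations, which isolates the atlas statistics from fitting noise;
the fitting stage is validated separately on rasterized subjects.

Passing tests demonstrate internal correctness — recovery of known
ground truth under the generator's assumptions — not clinical
validity. The generator does not emulate image intensities, papillary
muscles/trabeculations, breath-hold misregistration, tracker texture
noise, or regional wall-motion abnormalities (the scar itself); group
differences enter only through the global shape parameters. Results on
real CMR would additionally depend on segmentation quality and tracker
behaviour, which are outside this package's scope.
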