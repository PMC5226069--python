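# rvatlas

Statistical shape-atlas and strain analysis of the **systemic right
ventricle** in hypoplastic left heart syndrome (HLHS), packaged as a
desk-scale, fully testable pipeline with a synthetic CMR cohort
generator standing in for clinical data.

After a Norwood procedure the right ventricle becomes the systemic
pumping chamber, and the two shunt strategies (modified Blalock–Taussig
shunt vs. right-ventricle-to-pulmonary-artery conduit) are suspected to
remodel it differently. The analytical machinery for that question is
what this package implements:

* **Synthetic cohort generator** (`rvatlas.synthetic`) — two-group,
  two-stage cohorts of idealized crescent-section RV anatomies (NIfTI
  label stacks with an LV landmark) and cine contour sequences with
  *exact* ground truth for volumes, ejection fraction and strain.
* **Mesh personalization** (`rvatlas.personalize`) — labelled
  short-axis stack → pose-standardized, corresponded endo+epi mesh
  (1152 vertices → a 3456-entry shape vector) with a mean
  point-to-surface `fitting_error_mm` quality metric.
* **Ventricular geometry** (`rvatlas.geometry`) — Simpson
  slice-summation volumetry (EDV, ESV, SV = EDV−ESV,
  EF = (EDV−ESV)/EDV × 100), myocardial mass, length/diameter/
  sphericity/wall-thickness indices, Haycock BSA, allometric indexing
  (volumes / BSA^1.3, lengths / √BSA), tricuspid-regurgitation grading.
* **Shape atlas** (`rvatlas.atlas`) — mean-centred PCA over the pooled
  shape vectors; the 10 dominant *anatomical modes*, per-subject mode
  scores, ±k SD mode reconstructions, and mode-wise one-way ANOVA with
  Bonferroni correction across the tested modes.
* **Strain analysis** (`rvatlas.strain`) — contour propagation through
  label cines, segmental and global Lagrangian strain and strain rate
  (longitudinal at 4-chamber; circumferential and radial at basal, mid
  and apical short-axis levels) with systolic/diastolic peak extraction.
* **Cohort statistics** (`rvatlas.stats`) — Shapiro–Wilk, unpaired
  t-tests, χ² tests, ANOVA + Bonferroni post hoc, two-way random
  absolute-agreement ICC(A,1), and assembly of the four study-style
  report tables.

## Worked example

```python
import rvatlas.synthetic as syn, rvatlas.personalize as per, rvatlas.geometry as geo

template = syn.generate_template()                       # 3456-variable RV template
params = syn.ShapeParams(sphericity_factor=0.93, noise_sd_mm=0.4)
mesh = syn.deform_shape(template, params, seed=11)       # one synthetic subject
stack = syn.rasterize_segmentation(mesh, voxel_mm=1.5, slice_thickness_mm=5.0)

fitted = per.fit_template(per.standardize_pose(stack), template)
bsa = geo.haycock_bsa(8.5, 70.0)                         # weight kg, height cm
edv = fitted.cavity_volume_ml()
print(f"fitting error    : {fitted.fitting_error_mm:.2f} mm")
print(f"BSA (Haycock)    : {bsa:.3f} m2")
print(f"EDV              : {edv:.1f} ml   (ground truth {mesh.cavity_volume_ml():.1f} ml)")
print(f"indexed EDV      : {geo.allometric_index(edv, bsa, 'volume'):.1f} ml/BSA^1.3")
print(f"sphericity ratio : {geo.geometric_indices(fitted)['sphericity_ratio']:.2f}")
```

prints

```
fitting error    : 0.30 mm
BSA (Haycock)    : 0.413 m2
EDV              : 32.4 ml   (ground truth 33.2 ml)
indexed EDV      : 102.3 ml/BSA^1.3
sphericity ratio : 1.07
```

i.e. the personalization recovers this subject's ventricle to 0.30 mm
(sub-voxel at 1.5 mm imaging resolution) and its cavity volume to ~2%,
and the indexed EDV of ~102 ml/BSA^1.3 marks it as a dilated systemic
RV. Building the atlas over a full 93-subject synthetic cohort and
comparing mode scores between shunt groups then flags the dilation/
sphericity modes as the significant shape differences — the same kind
of single-mode finding the method is designed to expose:

```python
from rvatlas.atlas import build_atlas, compare_modes, explained_variance
from rvatlas.experiments import cohort_shape_vectors

X, labels, _ = cohort_shape_vectors(syn.default_cohort_config(seed=1))
atlas = build_atlas(X, k=10)
cmp = compare_modes(atlas.scores, labels)    # Bonferroni over the 10 modes
```

A command-line interface mirrors the pipeline
(`rvatlas simulate / fit / metrics / atlas-build / atlas-compare /
strain / report`); see `rvatlas --help`.

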