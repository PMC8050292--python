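# radrobust

Robustness analysis of CT radiomic features across reconstructed slice
thicknesses.

## The problem

Radiomic studies extract quantitative shape, intensity and texture features
from CT scans as candidate imaging biomarkers. In realistic cohorts the same
acquisition is often reconstructed at different slice thicknesses (typically
2.0 mm and 5.0 mm), and many texture features are not reproducible across
that change because of two intrinsic dependencies:

* **grey-level quantisation** — texture matrices (GLCM, GLDM, GLRLM, GLSZM,
  NGTDM) are built on re-binned Hounsfield intensities, and the number of
  grey levels Ng changes the feature values;
* **ROI volume** — additive features scale with the number of voxels *N* in
  the region of interest, and *N* changes with slice thickness and with any
  voxel-size resampling.

`radrobust` implements a complete, software-agnostic pipeline to quantify
and mitigate both effects, aimed at radiomics researchers validating feature
stability before modelling. Because clinical CT cohorts of this kind are not
openly redistributable, the package ships a synthetic phantom generator that
produces paired thin/thick reconstructions of the same latent volume with
tumour-like and muscle-like ROIs, so every stage runs end-to-end out of the
box.

## The methods

**Optimal grey-level count.** The Freedman–Diaconis rule gives a data-driven
bin count for the ROI intensity distribution X with *N* voxels:

    width = 2·IQR(X) / N^(1/3),    n_bins = (X_max − X_min) / width

The cohort median of this value is added to the standard sweep
{8, 16, 32, 64, 128, 256}. Features whose intraclass correlation across the
sweep, ICC(3,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E), falls below 0.9 are
classified as grey-level dependent, and per-setting variance collapse is
summarised with the normalised standard deviation σ_n = sd(f)/|median(f)|.

**Voxel-count dependency correction.** Features with Spearman |r_S| ≥ 0.5
against the voxel count are fitted, after binning measurements into
variable-width divisions of approximately equal occupancy, with eight
invertible candidate forms

    y = p1·g(x) + p0,   g ∈ {x, x², x³, 1/x, 1/x², 1/x³, log x, 1/log x}

by weighted least squares (weights from per-division spread). The form with
the smallest reduced χ² is inverted, y′ = (y − p0)/g(x), which on the exact
model returns the volume-free coefficient p1. Shape features are never
corrected — volume information is inherent to them. The corrector is exposed
as a scikit-learn transformer (`VolumeDependencyCorrector`).

**Cross-thickness robustness.** Per subject and feature,
Δr = |f_thick − f_thin| / |f_thin|; features with cohort-median Δr > 0.5 at
the original voxel sizes are corrected before the final comparison. A
feature is *robust* when its median Δr < 0.5 and *highly robust* when
< 0.25. As an alternative route, texture features are normalised by the
matched muscle ROI, ρ = f_tumour/f_muscle, and compared via
Δρ = |ρ_thick − ρ_thin| / |ρ_thin|.

The feature catalogue is the standard 107-feature set (shape 14,
first-order 18, GLCM 24, GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5), computed in
3D with no image filters, with grey-level quantisation over the per-ROI
intensity range.

## Worked example

```python
import numpy as np
from radrobust import (
    PhantomCohortSpec, generate_phantom_pair, extract_features,
    QuantisationConfig, VolumeDependencyCorrector, delta_r,
)
from radrobust.phantom import generate_cohort_feature_tables
from radrobust.extraction import ExtractionConfig
from radrobust.volumes import ResamplingConfig

spec = PhantomCohortSpec(n_subjects=8, seed=3)
table = generate_cohort_feature_tables(
    spec, [ExtractionConfig("original", ResamplingConfig(), QuantisationConfig(n_bins=40))]
)
thin = table[(table.tissue == "tumour") & (table.thickness_mm == 2.0)].set_index("subject_id")
thick = table[(table.tissue == "tumour") & (table.thickness_mm == 5.0)].set_index("subject_id")

dr_energy = np.median(delta_r(thin["firstorder_Energy"], thick["firstorder_Energy"]))
print(f"Energy median delta_r (uncorrected): {dr_energy:.3f}")

est = VolumeDependencyCorrector().fit(thin[["n_voxels", "firstorder_Energy"]])
fit = est.fits_["firstorder_Energy"]
print(f"best fit: form {fit.label}, p1 = {fit.p1:.1f}, reduced chi2 = {fit.reduced_chi2:.2f}")
thin_c = est.transform(thin[["n_voxels", "firstorder_Energy"]])
thick_c = est.transform(thick[["n_voxels", "firstorder_Energy"]])
dr_corr = np.median(delta_r(thin_c["firstorder_Energy"], thick_c["firstorder_Energy"]))
print(f"Energy median delta_r (corrected):   {dr_corr:.3f}")
```

Output:

```
Energy median delta_r (uncorrected): 0.618
best fit: form x, p1 = 4883.2, reduced chi2 = 0.03
Energy median delta_r (corrected):   0.079
```

First-order Energy (the sum of squared HU values) is additive in the number
of voxels, so thick-slice reconstructions — with ~2.5× fewer voxels for the
same physical tumour — report a ~60% smaller value. The engine identifies
the linear form (p1 ≈ 4883 is the per-voxel energy, i.e. the cohort's mean
squared HU of ≈ 70²), and dividing out the fitted dependence brings the
median cross-thickness difference from 0.62 down to 0.08, i.e. from "not
robust" to "highly robust".

The full pipeline (volume agreement, grey-level sweep, dependence screen,
correction and both robustness routes) runs as one call:

```python
from radrobust import PipelineConfig, run_pipeline
bundle = run_pipeline(PhantomCohortSpec(n_subjects=10, seed=1), PipelineConfig())
```

or from the shell: `radrobust all --seed 1 --outdir out/`.

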