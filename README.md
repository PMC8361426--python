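# cordbold

Analysis pipeline linking **cervical spinal-cord compression severity** to
**motor-network fMRI activation** in degenerative cervical myelopathy (DCM).
It is aimed at imaging researchers who want the full measurement chain —
cord morphometry, rater reliability, per-subject BOLD statistics, ROI
summaries and cohort correlations — as tested, reusable code that runs
end-to-end on synthetic data with known ground truth.

## What it computes

**Compression-volume morphometry.** A binary cord segmentation is reduced
to the per-slice cross-sectional area profile A(z) (voxel count × in-plane
voxel area, inferior → superior). The compressed interval [z₀, z₁] is
detected from the rate of change of the (smoothed) profile: a region opens
where dA/dz < −τ·A_base and closes where the recovering slope falls back
below +τ·A_base (default τ = 0.05 per slice). Inside the interval the
pipeline reports both the cord volume Σ A(z)·Δz (the headline *total
compression volume*) and the deficit Σ max(0, A_base − A(z))·Δz relative
to the baseline area A_base (median of slices outside detected regions).

**Reliability.** Repeated measurements by multiple raters are summarized
with intraclass correlations: ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E
+ k(MS_C − MS_E)/n) for inter-rater absolute agreement and the one-way
ICC(1,1) = (MS_B − MS_W) / (MS_B + (k−1)MS_W) for intra-rater repeats.

**Block-design BOLD GLM.** The task regressor is the alternating
rest/active boxcar (11 segments × 30 s at TR 1 s → 330 volumes) convolved
with a double-gamma HRF h(t) = g(t; 6, 1) − ⅙·g(t; 16, 1). Voxelwise OLS
with intercept and six motion nuisance regressors yields task betas,
percent BOLD signal (beta scaled by the regressor's rest-to-plateau range
over the voxel baseline), and Z statistics. Activation is thresholded at
Z > 3.1 and cluster sizes are tested against a corrected alpha by
sign-flip permutation of reduced-model residuals (or a Gaussian
random-field approximation).

**ROI metrics and associations.** For each run, percent BOLD and volume of
activation (VOA) are extracted for contralateral M1/S1/SMA/PMC and
bilateral cerebellum/putamen/caudate/thalamus, then correlated across the
cohort (Pearson r, two-sided p) with compression volume, mJOA disability
scores and symptom duration.

All inputs can be generated synthetically (`cordbold.synth`): cord
phantoms with analytic compression volumes, BOLD runs with known percent
signal, rater tables with chosen variance components, and Gaussian
cohorts with a target correlation structure. The packaged
`cordbold.load_dcm_cohort()` table carries the 23-patient clinical
characteristics used by the cohort-level checks.

## Worked example

```python
from cordbold import synth
from cordbold.morphometry import analyze_mask

spec = synth.CordPhantomSpec(
    n_slices=60,
    compressions=(synth.CompressionSpec(center_slice=30, extent_slices=5,
                                        max_area_reduction=0.4),),
)
mask, truth = synth.make_cord_phantom(spec)
profile, regions = analyze_mask(mask)
r = regions[0]
print(f"detected slices [{r.z_lo}, {r.z_hi}], "
      f"volume {r.cord_volume_in_region:.1f} mm3, deficit {r.volume_deficit:.1f} mm3")
print(f"analytic truth  [{truth[0].z_lo}, {truth[0].z_hi}], "
      f"deficit {truth[0].volume_deficit:.1f} mm3")
```

prints

```
detected slices [28, 32], volume 135.9 mm3, deficit 89.7 mm3
analytic truth  [28, 32], deficit 90.5 mm3
```

i.e. the slope-rule detector finds the 5-slice compression exactly and the
measured volume deficit is within digitization error (here 0.8%) of the
analytic value 0.4 · πr² · 5 · Δz.

The numbered drivers under `analysis/` run the full study-shaped analysis
and write tables to `results/`: `01_cohort_table.py` (validates the
patient table and reproduces mJOA 9.9 ± 2.1, age 65 ± 13),
`02_morphometry_recovery.py`, `03_reliability.py`, `04_bold_glm.py`,
`05_roi_metrics.py`, `06_associations.py`. A thin CLI (`cordbold morph`,
`cordbold icc`, `cordbold glm`, `cordbold associate`, `cordbold pipeline
demo`) exposes the same stages for single files.

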