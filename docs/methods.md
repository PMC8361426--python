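# Methods

This note documents the models, defaults and numerical choices behind
each stage, what the synthetic data do and do not emulate, and the known
limitations.

## Cord compression morphometry

The measurement operates on a binary cord segmentation (segmentation
itself is upstream and out of scope). Masks are reoriented to canonical
RAS so axial slices run inferior → superior along the last axis; slice
indices are 0-based with inclusive region limits.

*Area profile.* A(z) = (voxel count in slice z) × in-plane voxel area.
Slices with no cord voxels contribute zero area; anisotropic in-plane
voxels trigger a warning but are handled (area = dx·dy per voxel).
Volume bookkeeping is exact: Σ A(z)·Δz equals voxel count × voxel volume.

*Detection rule.* The profile is moving-average smoothed (default window
3 slices; truncated windows at the edges so constants pass through) and
its central difference is scanned. A region opens at the first slice with
slope < −τ·A_base and closes, after the slope has exceeded +τ·A_base
(recovery), where it falls back below that threshold; τ defaults to 0.05
of the baseline area per slice. Because smoothing spreads each notch by
half a window, the limits are then localized on the *raw* profile as the
maximal run of slices below A_base − τ·A_base around the detected notch.
Regions shorter than `min_extent` (default 3 slices) are discarded.
The exact derivative rule and thresholds of the original instrument are
unpublished; these defaults recover box- and Gaussian-shaped phantom
compressions across extents 3–15 slices and depths 20–60% with zero edge
error and sub-1% deficit error, without false positives at realistic
surface noise.

*Baseline.* A_base is the median area over slices outside detected
regions, estimated iteratively: first pass with the global median of
nonzero slices, one refinement pass after exclusion. The median makes the
estimate robust to the compression's own pull.

*Volume metrics.* Both readings of "total compression volume" are always
computed: `cord_volume_in_region` = Σ A(z)·Δz over the interval (the
shaded-area reading, the default headline metric) and `volume_deficit` =
Σ max(0, A_base − A(z))·Δz (volume lost). Empty slices inside a region
contribute zero area, i.e. the maximal per-slice deficit — conservative
under segmentation dropout. When several regions are detected the
subject-level value is their sum; single compression sites are the
typical clinical presentation, so the sum is an extension, not a
requirement.

## Cord phantoms

Each slice is a digital disk: voxel centres with x² + y² ≤ r(z)² in
physical mm, matching the lattice-count oracle used in tests. Compression
is applied to *area*, not radius — r(z) = r₀√(1 − ρ(z)) — so the ground
truth deficit Σ ρ(z)·πr₀²·Δz stays analytic. Box compressions reduce a
contiguous interval by a constant fraction; Gaussian compressions use a
bell-shaped ρ(z) whose FWHM is the stated extent (their reported truth
interval is the FWHM span, and the deficit is integrated over it).
Default in-plane resolution is 0.125 mm so rasterization error in the
deficit stays well under the 5% recovery tolerance even for shallow
notches. Surface noise is per-voxel boundary roughness: each voxel's
inclusion radius is jittered by N(0, σ) mm, emulating segmentation
jitter, which largely averages out around the perimeter — per-slice area
noise stays small, and the measured deficit varies by < 1% (CV) across
seeds at σ = 0.2 mm. A single seed drives each generator call;
noiseless phantoms are seed-independent.

## BOLD simulation and GLM

*Paradigm.* Alternating rest/active segments, starting at rest by
default; the study protocol is 11 × 30 s at TR 1 s → 330 volumes with
150 active samples. Segment duration must divide evenly by TR.

*HRF.* h(t) = g(t; a₁=6, b₁=1) − c·g(t; a₂=16, b₂=1) with c = 1/6,
sampled at TR over 32 s and normalized to unit peak (positive-lobe mean
6 s, undershoot mean 16 s — the canonical convention; all parameters are
configurable and recorded in output metadata). The kernel is zero at
onset and has exactly one sign change.

*Percent-signal convention.* The phantom defines truth as the
plateau-to-rest swing in percent of the rest baseline. The GLM reports
psc = 100·β·ptp(x) / (β₀ + β·min(x)), where x is the convolved task
regressor and β₀ the intercept: the denominator is the voxel's fitted
signal at the regressor's rest level, which makes noiseless closed-loop
recovery exact (to ~1e-12) rather than approximate.

*Fit.* Ordinary least squares per voxel on [intercept | task | six
demeaned motion regressors]. t = β/SE is mapped to Z through matching
t and normal tail probabilities (capped at |Z| = 37, beyond float64 tail
resolution). Temporal autocorrelation is **not** modelled and degrees of
freedom are nominal: the simulator generates white noise, for which the
Z calibration is exact (null Z maps pass a KS test against N(0,1)); on
real scanner data this is a deviation that would inflate Z, and
prewhitening would be required.

*Smoothing.* Gaussian with σ = FWHM/(2√(2 ln 2)) per axis, converted to
voxels; the default `inplane` mode smooths each axial slice in 2-D
(matching the per-slice description of the original processing), with
`isotropic3d` available. Reflective boundaries preserve the image mean.

*Cluster inference.* Suprathreshold voxels (Z > 3.1 by default) are
grouped by 26-connectivity. Cluster-level corrected p uses, by default,
sign-flip permutation of reduced-model residuals: the task column is
dropped, residuals are sign-flipped per timepoint (valid for
exchangeable symmetric errors), the full model is re-fit and the maximum
suprathreshold cluster size rebuilt ≥ permutation-count times;
p = (1 + #{max ≥ observed})/(n_perm + 1). This is exact at simulation
scale and needs no smoothness estimation. A stationary Gaussian
random-field approximation (expected-EC cluster count with residual-based
FWHM estimation and the exponential cluster-extent model) is provided for
fidelity to conventional neuroimaging tooling and is flagged as
approximate. Whether the original "Z > 3.1, P = 0.001" used 0.001 as the
cluster-forming or the cluster-level alpha is ambiguous; both are
configurable and neither is hard-coded.

## ROI metrics

Percent BOLD is the mean percent signal over ROI ∩ cluster-surviving
voxels (the whole-ROI mean is emitted alongside for sensitivity, since
which average the original analysis used is unstated); VOA is the
suprathreshold voxel count in the ROI times the voxel volume. An empty
intersection yields 0 with an audit flag rather than a missing value, so
every subject contributes to the cohort correlations ("no significant
activation" is informative). Cortical metrics (M1, S1, SMA, PMC) are
taken from the hemisphere contralateral to the tapping hand; subcortical
metrics (cerebellum, putamen, caudate, thalamus) from bilateral masks.
Probabilistic atlas maps are binarized at 25% by default (common
convention, configurable). Atlas files are inputs, not bundled; the test
surface uses a synthetic box-ROI layout with the same names and
lateralization.

## Reliability

Inter-rater reliability uses ICC(2,1) — two-way random effects, absolute
agreement, single measurement — because the clinically relevant question
is whether two specific raters produce interchangeable absolute values.
Repeats are averaged within rater first (the design takes three repeats
per rater); `summarize_repeats="all"` keeps them as columns.
Intra-rater reliability uses the one-way ICC(1,1) over one rater's
repeats. The original publication does not state its ICC model, so the
model label and mean squares are always reported to keep the choice
auditable. Negative estimates are reported as computed with a flag,
never truncated — truncation would hide degenerate designs. Balanced
designs are required; missing cells are listed in the error.

## Cohort generation and associations

Cohorts are drawn from a multivariate Gaussian with a target correlation
matrix (validated symmetric, unit-diagonal, PSD; sampled through an
eigendecomposition factor so the PSD boundary is allowed) and per-variable
mean/SD marginals; mJOA columns are rounded and clipped to the 0–18
integer scale afterwards. Default targets follow the printed effect
sizes the analysis emulates (compression–%BOLD 0.56, compression–VOA
0.55, mJOA–compression −0.36, mJOA–%BOLD −0.50); compression-volume
marginals are configurable rather than matched, since their distribution
is not reported. Empirical correlations converge to the target (checked
at n = 10⁴ within 0.02) and the mean sample r at n = 23 recovers 0.56
within 0.05 over 500 draws.

Pearson r uses the product-moment formula with a two-sided p from
t = r√((n−2)/(1−r²)). The battery reports per-pair uncorrected p values
(matching the bivariate analysis it reproduces) plus a
Benjamini–Hochberg column for the reader; pairwise-complete cases are
used with per-pair n reported; constant variables yield a flagged NaN
row rather than aborting the battery. Two-sided tests are assumed
throughout.

## Pipeline and problem sizes

`run_pipeline` couples all stages through one latent severity per
subject (deeper compressions ↔ larger true percent signal ↔ lower mJOA),
so the demo recovers positive compression–activation and negative
mJOA–activation correlations from fully synthetic imaging. Every stage
writes a JSON sidecar (parameters, seed, package version) and the run
manifest links all outputs; re-runs with the same seed are byte-identical.

Simulation sizes are chosen so the whole suite and the acceptance script
each run in about a minute on one CPU: GLM calibration uses 12³-scale
volumes and 110-volume runs (11 × 10 s segments) with 200 permutations
and 100–200 null simulations; the closed-loop percent-signal checks use
the full 330-volume paradigm at small matrix size, where recovery is
resolution-independent. The familywise-error check is a one-sided bound
(the permutation test is conservative under discreteness of small
volumes).

## What the synthetic data do not show

The phantoms contain no scanner physics: no physiological noise, spikes,
distortion, slice-timing effects or true motion (motion traces exist as
nuisance regressors, but the images are not actually displaced), no
anatomically realistic cord or brain geometry, and white — not
autocorrelated — noise. Passing tests therefore demonstrate correctness
of the estimators under their stated assumptions, not robustness to real
acquisition artifacts; the preprocessing that would address those
(registration, distortion and motion correction) is explicitly upstream
of this package.
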