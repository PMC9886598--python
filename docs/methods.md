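# Methods

This note documents the models, estimators, and numerical choices behind
`multifc`, and what the synthetic phantom does and does not establish about
real data.

## Phantom signal model

Each simulated run lives on a single native grid holding a toy
parcellation: 7 × `parcels_per_network` compact parcels (gray matter), one
WM slab and one CSF slab.  The voxel time series in parcel p of network k is

    x_v(t) = √c_k · s_k(t) + √(1 − c_k) · η_p(t),

where s_k is the network signal, η_p a noise series shared by the voxels of
parcel p, and c_k ∈ [0, 1] the within-network coupling.  Both s_k and η_p
are Gaussian white noise hard-band-passed to 0.01–0.1 Hz and rescaled to
unit variance — the simplest process with the spectrum the analysis
assumes.  Because signal and noise occupy the same band, band-pass
filtering leaves the correlation structure intact, and because η is shared
within a parcel, the expected Pearson correlation between two same-network
series — voxel-level across parcels or parcel-mean level — is exactly c_k.
This identity is the phantom's central calibration: the within-network FC
features should recover atanh(c_k) up to sampling error and thermal-noise
attenuation.

Patients (group = 1) have c reduced by `group_delta` in designated networks
(default: somatomotor and limbic, mirroring where pooled patient-control
differences are typically reported).  The whole volume is then scaled by a
site gain, shifted by a site offset, and corrupted by white thermal noise;
WM and CSF voxels carry shared nuisance signals, whose realized
compartment means are recorded in the confound table.  Motion traces are
six-parameter random walks with translation step sd `motion_sd` (mm) and
rotation step sd `motion_sd`/50 (rad), so that translations and
rotation-induced displacement on the 50 mm sphere contribute comparably to
FD; the implied mean FD is ≈ 4.8·`motion_sd`.

The four default sites emulate realistic acquisition heterogeneity: TR
1.5 s or 3.0 s, 140–240 volumes, voxel sizes from 1.875 × 1.875 × 4 mm to
4 mm isotropic, gains/offsets/noise chosen so that median tSNR spans
roughly 45–90, and motion levels spanning mean FD ≈ 0.04–0.19 mm.

Site effects on the *features* are applied by `inject_site_effects`
(y → scale·y + shift per site) at the feature-table level, not the voxel
level, with the ground truth retained in table metadata.  This separation
keeps the ComBat recovery experiment clean while the voxel-level
gain/offset independently stresses the quality metrics.  Note that scaling
a full feature value also scales its mean and covariate part; the exact
residual location/scale model (site effects acting on the noise term only)
is used where parameter recovery is asserted quantitatively.

The feature-level generator `simulate_feature_table` draws the ten features
directly from y = μ + β·x + δ·group + ε with within-network Fisher-z means
0.22–0.40 (sd 0.1), global-map means 0.10–0.15 (sd 0.08), a mild age slope
(−0.002 z/year), ages uniform on 25–55 years, and sex Bernoulli(0.5).  It
exists because harmonization properties are statements about feature
distributions and do not require image simulation.

**What the phantom does not model:** hemodynamic response functions,
anatomy, field inhomogeneity, slice timing, spatially correlated noise,
lesions, or realistic artifact topographies.  Passing tests therefore
demonstrate the correctness of the estimators and the harmonization
machinery under the stated generative model, not robustness to every
real-world artifact.

## Quality metrics

- **tSNR**: temporal mean / sample sd (n−1 denominator) per voxel;
  temporally constant voxels get tSNR 0 and are excluded from the median,
  mirroring common QC-tool behavior.
- **FD**: Power-style sum of absolute parameter differences with the 50 mm
  rotation lever arm; the first frame is 0 by convention and excluded from
  the mean.  The exclusion rule is strict: mean FD > 0.25 mm excludes, a
  run at exactly 0.25 mm is retained.
- **Standardized DVARS**: raw DVARS(t) (RMS over in-mask voxels of the
  backward difference) divided by the RMS of the per-voxel
  difference-series sds.  The normalizer makes the metric exactly invariant
  to affine intensity rescaling, which is the property the standardization
  is meant to deliver; a whole-brain single-sd reading of the normalizer
  would be equally scale-invariant but mixes spatial and temporal variance.
- **FWHM**: after removing each voxel's temporal mean, the lag-1 spatial
  autocorrelation per axis is ρ_k = 1 − s²_diff,k/(2s²); under a Gaussian
  autocorrelation function FWHM_k = Δ_k √(−2 ln 2 / ln ρ_k).  Axes with ρ
  outside (0, 1) are skipped for that volume; axes combine by geometric
  mean, volumes by arithmetic mean.  For white noise smoothed with a
  Gaussian kernel this estimator recovers the kernel FWHM exactly in
  expectation (the lag-1 ACF of the smoothed field is exp(−Δ²/4σ²)), which
  is the calibration the tests assert to within 10%.

## Preprocessing

Confound regression projects each voxel series onto the complement of
[intercept | confounds] (collinear columns dropped, voxel mean re-added so
intensity-scaled quantities stay meaningful), followed by a hard FFT
band-pass retaining 0.01 ≤ f ≤ 0.1 Hz.  The hard mask was chosen over an
IIR filter because the band edges are the only stated specification and the
projection is exactly idempotent, making pass/stop-band behavior testable
to machine precision.  Regression and filtering are sequential (regression
first).  Smoothing is separable Gaussian with σ_k = FWHM/(2.3548·Δ_k) and
mask renormalization (divide by the smoothed mask) so edge voxels average
only in-mask neighbors.  Map z-standardization uses moments over the whole
analysis (brain) mask while the global averages are taken over GM; if the
two supports coincided the global mean would be identically zero, so the
distinct supports are what make the global features informative.

## Features

Parcel series are spatial means; correlations are Pearson, clipped to
±(1 − 1e−7) before atanh so degenerate parcels stay finite.  Within-network
FC averages the strictly positive z values over unique within-network pairs
(negative correlations are excluded as interpretively ambiguous); a network
with no positive edge yields a flagged-missing value with a warning, and
the pipeline drops such subjects before harmonization (recorded in
`missing_features.tsv`).  ALFF is the mean of single-sided FFT amplitudes
2|X_k|/T over in-band bins, computed after confound regression but before
band-pass filtering (the filter would trivially reshape the spectrum being
measured); mean rather than sum of bins is used, which differs only by a
constant for fixed band and run length.  ReHo is Kendall's W over the ≤ 27
in-mask series of the 3×3×3 neighborhood without tie correction (continuous
BOLD values make ties measure-zero); edge voxels use a shrunken
neighborhood (K ≥ 2) rather than being discarded, keeping small grids
usable.  Weighted degree centrality sums correlations strictly above
r = 0.25 over all other analysis-mask voxels; the implementation is checked
against an O(N²) brute-force oracle.

## Harmonization

`fit_combat` follows the parametric empirical-Bayes ComBat algorithm:
least-squares location model with site effects constrained to a
site-size-weighted zero mean (identifiability; α is then the grand
intercept), pooled residual variance with the 1/N denominator, per-site
standardized means/variances, normal and inverse-gamma hyperpriors fitted
across features by method of moments, and iterated conditional-posterior
updates to convergence (max relative change < 1e−4, cap 200 iterations) —
the reference implementation's criterion.  Age is centered before
regression for conditioning; sex and group are coded 0/1.  All ten features
are harmonized jointly: the features share the cohort and the EB priors
benefit from pooling across them, and the reference workflow harmonizes a
feature matrix as one block.  The output is tested to equal the standard
R implementation to 1e−6 on identical inputs.

Site effects are only identified relative to the weighted-mean constraint,
so recovery of injected effects is asserted on between-site contrasts
(γ*_i − γ*_j in feature units, δ*_i/δ*_j), averaged over the feature
profile: per-feature δ̂ at 50 subjects/site has sampling sd ≈ δ/√(2n) ≈ 0.2,
so a 10% per-feature claim would be noise-limited, while the profile mean
recovers both parameters within 10%.  Under a null (no site effects), the
adjustment changes values only through estimation noise in γ*/δ*, which
scales like 1/√n; at 400 subjects/site the mean absolute change stays below
0.05 feature sd.

## Statistics

All tests are two-sided at α = 0.05.  Kruskal–Wallis, Dunn, and
Fligner–Killeen use their tie-corrected rank formulations; Wilcoxon uses
the tie-corrected normal approximation with continuity correction; the
chi-squared test omits the Yates correction (this exactly reproduces the
published contingency statistics recomputed from the printed counts); t
tests are Welch/Satterthwaite, with a summary-statistics entry point for
table-style inputs.  The correlation screen applies Bonferroni over all
site × feature × metric tests performed.  Group comparisons pool patients
across sites after harmonization and per-site covariate adjustment (age,
sex, mean FD; residuals re-centered on the site feature mean).  Everything
is validated against reference implementations to ≤ 1e−8 on randomized
instances, and the type-I error of the two rank tests is verified within
±2% of nominal by simulation.

## Problem sizes and determinism

The default simulated cohort is 4 sites × 15 subjects on a 24×24×12 grid
with 98 parcels of 8 voxels; one subject takes ≈ 1 s end to end.  The
harmonization experiments use feature-level tables (4 × 50 subjects, 100
replicates; 200 patients vs 100 controls for the group-effect experiment),
and the coupling-recovery experiment uses 50 single-subject runs at 200
volumes — sizes at which every asserted property holds with a comfortable
margin while the whole suite stays fast.  Every stochastic stage takes an
explicit integer seed; cohorts derive per-subject seeds from the master
seed, and identical seeds give bit-identical outputs.

## Known limitations

- The toy parcellation is geometric; there is no spatial correspondence to
  a real atlas, though real atlas + mask NIfTI inputs flow through the same
  interfaces.
- Spatial normalization to a template is out of scope: all computation
  happens on one native grid per cohort, so "whole brain" means the
  analysis mask.
- The DVARS normalizer and the FWHM axis-combination rule are reasonable
  conventions among several in circulation; both choices are documented
  above and made exactly testable, but other tools may differ by a
  constant factor.
- ComBat assumes the location/scale site-effect model; site effects that
  alter covariate slopes are removed only approximately.
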