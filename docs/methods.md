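# Methods

This note documents the models and procedures implemented in `oscillonet`,
the parameter defaults and why they were chosen, the numerical conventions,
what the synthetic-data generators do and do not emulate, and known
limitations.

## Spectral model and parameterisation

A channel's power spectrum is modelled in log10-power as an aperiodic
background plus Gaussian oscillatory peaks:

    log10 P(f) = b − χ·log10 f + Σᵢ aᵢ·exp(−(f − cᵢ)² / (2 wᵢ²))

- `b` — offset (log10-power intercept at 1 Hz).
- `χ` — aperiodic exponent (unitless, ≥ 0 in generated data; unconstrained
  in fitting). The knee-free form is used throughout: the fitted range
  (default 1–100 Hz) sits within a single power-law regime, and no knee
  configuration is exposed.
- `cᵢ, aᵢ, wᵢ` — peak center (Hz), height above background (log10-power,
  the "pw" parameter), and Gaussian SD width (Hz). The configured peak
  width limits [0.5, 12] Hz bound the FWHM-like reported width 2·w, matching
  the convention of the reference parameterisation toolbox; the Gaussian SD
  is therefore clipped to [0.25, 6] Hz.

**Power spectra.** Signals are cleaned of zero-padding (runs of ≥ the
configured number of exact zeros are deleted; channels with under 10 s of
signal remaining are rejected by name). Time-frequency power uses complex
Morlet wavelets with 7 cycles; squared magnitudes are averaged over time,
excluding samples within half the wavelet support of either signal edge,
where the convolution is boundary-contaminated. Power is normalised per
frequency by the wavelet's gain on a unit sinusoid, so equal-amplitude
oscillations at different frequencies produce equal peak power (amplitude
convention rather than spectral density; the difference is a smooth
multiplicative factor absorbed by the aperiodic fit). The frequency grid
defaults to 1–100 Hz in 0.5 Hz steps (linear, configurable); the analysis
is grid-agnostic beyond resolution.

**Aperiodic fit.** An ordinary least-squares line in (log10 f, log10 P) is
made peak-resistant by clipping negative residuals to zero and refitting on
the bins at or below the 2.5th percentile of the clipped residual — i.e.
on the bins not lifted by peaks.

**Peak detection.** The flattened spectrum (log10 P minus the aperiodic
fit) is searched iteratively: the largest residual maximum exceeding the
detection threshold is modelled as a Gaussian (width from the half-height
crossing, clipped to the limits) and subtracted; the loop stops when no
point exceeds the threshold (or the optional peak-count cap is reached).
The threshold is `peak_threshold_sd` (default 2) times the SD of the
flattened spectrum, computed once before extraction. This fixed-threshold
convention — rather than recomputing the SD on the shrinking residual each
iteration — was chosen because it terminates cleanly on noiseless spectra
(a relative threshold on the residual is scale-free and can keep detecting
its own subtraction error) and because it makes the detected-peak count
provably monotone in the threshold multiplier. All Gaussians are then
refined jointly by bounded least squares.

**Full decomposition.** After peak fitting, the aperiodic component is
refitted by plain least squares on the peak-removed spectrum, and a final
joint refinement fits offset, exponent and all Gaussians simultaneously.
The joint step removes the residual bias the initial background fit picks
up under peak wings; on noiseless well-separated peaks the decomposition is
then exact to optimiser precision (the test suite bounds worst-case errors
over 200 random spectra at 0.5 Hz center, 5% height, 0.02 exponent —
observed errors are orders of magnitude smaller). The reported `fit_error`
is the mean absolute log10 residual of the final model and is recomputable
from the model by construction.

## Dominant-rhythm classification

Band scheme defaults ("results"): theta [4, 8), alpha [8, 13), beta
[13, 30), gamma [30, 100) Hz — half-open intervals, the 12–13 Hz gap folded
into alpha, and no beta/gamma overlap. An alternative "methods" scheme with
beta [13, 35) is selectable; the two differ only for channels whose largest
peak lies in [30, 35), which the test suite pins as a set-difference check.

Per band, the highest peak (ties to the lower center) is kept. Heights are
standardised sequentially — within electrodes, then within subjects, then
across the dataset — subtracting the group mean and dividing by the group
population SD (n, not n−1); degenerate groups (single member or zero SD)
are centred only and logged. Whether the three levels should be applied
sequentially or in some other combination is ambiguous in the source
description; sequential application was chosen, and because each stage is
an affine map shared by all of a channel's peaks, the within-channel argmax
— and hence every dominance label — is invariant to the choice, which the
test suite asserts. Winner-takes-all: the band with the highest
standardised peak is the channel's dominant rhythm; ties break to the
lower-frequency band, then the lower center. Channels with no fitted peak
are reported as "no dominant rhythm", never dropped silently.

Region assignment projects the MNI coordinate into a labelled parcellation
image (nearest labelled voxel within 5 mm as fallback, else "unlabelled");
hemisphere comes from the sign of x with |x| ≤ 2 mm as midline. The
hemisphere comparison is an uncorrected two-proportion chi-square
(Yates-corrected χ² would not give p = 1 for identical proportions).

## Network mapping

- Seeds: binary spheres, voxel = 1 iff its center lies within r (default
  5 mm) of the coordinate; r = 0 selects exactly the containing voxel.
- Smoothing: Gaussian kernel, SD 8 mm by default, converted per axis to
  voxel units from the affine; NaN-aware (normalised convolution) where
  maps contain missing data.
- Functional maps: per connectome subject, the seed time series is the mean
  over seed voxels; Pearson r to every voxel is Fisher z-transformed
  (|r| capped at 0.999999 to keep degenerate voxels finite) and averaged
  across subjects. Averaging in z rather than r was chosen for variance
  stabilisation, the standard in normative-connectome mapping. Grey-matter
  masking sets out-of-mask voxels to missing; the pipeline order is smooth
  → mask (the operations do not commute, and the test suite pins the
  order).
- Structural maps: a streamline is selected if any vertex lies within the
  seed radius (point-based, the default; a segment–sphere intersection test
  is available by flag). The map counts each selected streamline once per
  voxel traversed. Group aggregation is the voxel-wise missing-aware mean
  for functional maps and the exact sum for structural maps (streamline
  counts are additive; permutation-invariance and conservation are tested).
- Template grid: 2 mm isotropic MNI-like 91×109×91 by default,
  configurable; the affine is the single source of truth for mm↔voxel.

## Group statistics

Voxel-wise pooled-variance two-sample t (dof = nA + nB − 2 at fully
observed voxels; zero-variance voxels are missing), both one-sided
contrasts. Pooled variance rather than Welch mirrors the classical
two-sample design matrix and supports the unequal group sizes that
dominance splits produce.

FWE control defaults to permutation max-T: the null is the maximum voxel t
over group relabellings — all C(n, nA) relabellings enumerated when that
count is ≤ 10,000, otherwise `n_perm` random relabellings (default 1000;
seed required). A voxel is significant when its FWE-adjusted p (tail share
of null maxima; add-one estimator on the sampled path) is ≤ α. By symmetry
of label exchange the same null serves the mirrored contrast. Bonferroni
(α/V per voxel) is provided as a deterministic, conservative cross-check.
Permutation max-T was preferred over parametric random-field correction
because it is assumption-light and desk-verifiable against exhaustive
enumeration; under the null the family-wise rejection rate calibrates to α
(tested at 200 replicate datasets, 20 maps per group, 1000 voxels, 500
permutations).

## Molecular correlation

PET maps are resliced to a common grid (linear for intensities, nearest for
labels), z-scored across in-brain voxels per tracer — raw radioligand units
are not comparable, so "spatial normalisation" before averaging is
implemented as per-map intensity standardisation — and averaged into an
aggregate map. The compound parcellation claims voxels in atlas precedence
order (default: basal ganglia > cerebellum > cortex, so small subcortical
structures are not swallowed); fully shadowed regions are dropped, duplicate
names are suffixed, and the final region count is reported as data-dependent
rather than asserted. Per-parcel means of non-missing voxels give profiles;
compartment-restricted Spearman rank correlations get two-sided permutation
p-values — exhaustive enumeration when n! ≤ 10,000, otherwise the add-one
Monte Carlo estimator p = (1 + #{|ρ_perm| ≥ |ρ|})/(1 + n_perm), whose floor
at the default n_perm = 9999 is 1.0×10⁻⁴. The permutation null is
unrestricted (no spatial-autocorrelation-preserving rotation); a
variogram-preserving null would be a conservative extension and is out of
scope. Reports cross all maps × tracers × compartments with a
Benjamini–Hochberg column.

## Synthetic data: what it emulates, and what it does not

The generators are the test bed for every stage and are deterministic under
a user-supplied integer seed (no global RNG state; bit-identical re-runs).

- Spectra: exactly the model above plus iid Gaussian log10 noise; with
  noise 0 and peaks separated by more than 2(wᵢ+wⱼ) the fitting stage
  inverts them (the recovery property is tested).
- Time series: white noise shaped in the Fourier domain by the square root
  of the target spectrum, so each peak becomes a band-limited stochastic
  component; sampling rate ≥ 200 Hz enforced.
- Cohorts: each channel's true dominant band is drawn from configured
  probabilities (defaults are the observed dominance fractions
  0.156/0.224/0.566/0.052, renormalised from printed rounding); the truth
  is realised by making that band's peak strictly largest (margin ≥ 0.1
  log10-power) with optional secondary peaks kept well separated and away
  from band edges, so noiseless classification recovers the truth exactly.
  Coordinates default to a uniform cortical bounding box with symmetric
  hemispheres; subject assignment is random over a configured cohort size
  (default 106 subjects, 1772 channels, ECoG fraction 258/1772).
- Connectomes: voxels sharing a community label share a unit-variance
  latent signal plus iid noise of SD σ, so within-network r = 1/(1+σ²)
  (helper `noise_for_target_r` inverts this) and cross-network correlation
  is 0 in expectation.
- Tractograms: jittered copies of polyline bundle templates.
- PET maps: normal scores of the reference profile's ranks mixed with
  Gaussian noise at Pearson weight r = 2·sin(πρ/6) — the bivariate-normal
  Spearman↔Pearson relation — so the parcel means rank-correlate with the
  reference at the designed ρ (±0.1 at 200 parcels).

None of this emulates real neurophysiology beyond the spectral model:
no volume conduction, no head geometry, no haemodynamics, no spatial
autocorrelation in PET noise, no epileptiform contamination. Passing tests
therefore demonstrate that the pipeline's operations are correct and
calibrated under their stated models — not that the scientific conclusions
drawn from any particular real dataset would replicate.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data at
deliberately compact sizes chosen to exercise every code path: 200 spectra
for parameter recovery, a 1772-channel cohort for classification, 200
replicate null datasets (20 maps/group, 1000 voxels, 500 permutations) for
FWE calibration, 200 parcels for correlation recovery, and a coarse (4–8 mm)
MNI-like grid for the end-to-end demo. Floating-point ties in permutation
tails are handled with a 1e-12 slack in the ≥ comparisons; correlations are
computed in double precision; degenerate denominators (zero variance, empty
parcels, empty groups) are mapped to missing values or raised as named
errors, never silently propagated.

## Known limitations

- The aperiodic model has no knee; spectra with a bend inside the fitted
  range will bias χ.
- Peak detection assumes approximately Gaussian peaks on a log-power scale;
  strongly asymmetric or overlapping (< 2 SD separation) peaks may merge.
- The permutation FWE and correlation nulls assume exchangeability across
  maps and parcels respectively; spatially autocorrelated parcel profiles
  make the unrestricted correlation null liberal.
- Structural "connectivity" is streamline counting on provided tractograms;
  no tractography, distance weighting, or fibre validity assessment.
- Electrode localisation, epilepsy-channel screening, connectome and PET
  acquisition/preprocessing are upstream of this package and out of scope.
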