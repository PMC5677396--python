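# Methods

This note documents the models and procedures implemented in `soilhsi`,
the choices made where the design was genuinely open, and what the
synthetic cohort does and does not establish about real data.

## Reflectance correction and ROI extraction

Raw digital numbers are converted to percent reflectance per pixel per
band as I = (I0 − D)/(W − D) × 100, where W and D are white-tile and
closed-shutter reference frames.  White/dark frames may be full cubes or
single-line (1 × cols × bands) references broadcast across scan lines, the
natural shape for a push-broom line-scan instrument.  Any pixel/band where
W = D raises immediately rather than propagating NaN.  Reflectance is kept
on the 0–100 scale everywhere downstream.

ROIs are 0-based, half-open rectangles; `centered_roi` floors odd margins,
so a 50 × 50 window on a 100 × 100 frame starts at (25, 25).  ENVI I/O
supports bsq/bil/bip interleaves and uint8/int16/uint16/float32/float64
rasters; float64 output round-trips bit-exactly.

## Spectral preprocessing

The working window is 975–1645 nm, a closed interval (both endpoint bands
kept).  Preprocessing order is SNV on rows, then z-score on columns; the
order matters and is asserted in tests.  Both transforms use the sample
standard deviation (n − 1), the chemometrics convention; changing `DDOF`
in `soilhsi.spectra` flips the alternative.  z-score statistics are
estimated on the calibration split only and applied unchanged to the
prediction split.  Whether pooled or calibration-only scaling is the
"right" reading of common practice is ambiguous; the calibration-only
choice is the leakage-free one and is used throughout.  A constant
spectrum (SNV) or constant band (z-score) is an error naming the offending
sample or band, never a silent division by zero.

## SPA — successive projections algorithm

Phase 1 grows a chain from every candidate start band: at each step all
unselected columns are deflated by the newly selected one (accumulating
the projection onto the orthogonal complement of the selected span) and
the column of maximal projected squared norm is appended.  Ties break to
the lowest band index for determinism.  Chains stop early, with a warning,
when the maximal projected norm falls below 1e−10 × the largest initial
column norm (residual space numerically exhausted).  Equivalence with a
brute-force oracle that re-orthogonalises from scratch by QR at every step
is asserted exhaustively on random instances up to 12 × 8.

Phase 2 scores every chain prefix by the leave-one-out RMSECV of an
intercepted multiple linear regression, computed with the exact OLS
hat-matrix identity e_i/(1 − h_ii) (equivalent to n refits, verified
against a per-fold normal-equations oracle).  For each subset size m the
minimum over all chains is recorded, giving the RMSECV-vs-size curve.

The subset size is the smallest m with
RMSECV(m)² ≤ F_crit(α; n, n) · RMSECV_min², α = 0.25 by default, where n
is the calibration count — each RMSECV in the ratio pools n
cross-validation residuals.  The degrees-of-freedom convention is isolated
in `_f_critical` so it can be changed in one place.  Two numerical guards:
(i) when RMSECV_min is at machine-zero scale (noiseless data), a floor of
1e−8 × range(y) stands in for it so that "equal to the minimum" is decided
at a sensible scale; (ii) rank-deficient candidate subsets score +inf
rather than raising.

`max_vars` defaults to min(30, n_cal // 2).  Subsets approaching
n_cal − 2 variables leave a single residual degree of freedom in LOOCV,
and the minimum over ~200 chains then collapses at the largest sizes,
forcing the F-criterion to the maximal size whenever the smallest class
(28 calibration samples) is selected on.  Halving keeps the curve
interpretable at every cohort size used here while leaving the observed
selections (1–18 variables) unconstrained; an explicit `max_vars` is
honoured up to the hard bound min(n_cal − 2, n_bands).

For classification-mode selection the reference y is the 1/2/3 soil
category code treated as one continuous variable.  Regressing on an
ordinal code is scientifically questionable (it imposes an ordering and
spacing on categories), but it is the stated workflow this package
implements; the EW sets it produces behave sensibly in practice.

## GLCM texture features

Gray levels: each ROI band image is min–max scaled per image and
quantised to L = 64 levels by floor(v_norm · L) clipped to L − 1; a
constant image maps to level 0.  Per-image (rather than global) scaling
makes texture statistics invariant to the band's mean reflectance, which
is what the spectral features already encode; L = 64 balances gray
resolution against count sparsity on a 50 × 50 ROI (2 450 pixel pairs per
direction).  Co-occurrence offsets in image coordinates at distance 1:
0° → (0, +1), 45° → (−1, +1), 90° → (−1, 0), 135° → (−1, −1); symmetric
accumulation (both orderings), normalised to probabilities.  Statistics:
energy Σp², contrast Σ(i−j)²p, homogeneity Σp/(1+(i−j)²) (inverse
difference moment variant), entropy −Σp ln p with 0·ln 0 = 0, each
averaged over the four directions.  Alternatives (entropy base,
homogeneity denominator) live behind the formulas in one function each.

## Splitting, SVM, PLSR, metrics

Splits are random 2:1, stratified by class when labels are present:
floor(2n/3) per class to calibration, so (84, 57, 42) gives 56/38/28
calibration and 28/19/14 prediction samples, and a pooled unstratified 183
gives 122/61.  Splits are seeded and deterministic.

The SVM uses an RBF kernel with (c, g) from a grid over log₂c ∈ [−5, 15],
log₂g ∈ [−15, 5], step 2, by 5-fold stratified CV accuracy on the
calibration set.  Features are z-scored with calibration statistics before
the SVM so that spectral and texture blocks are commensurate after fusion
(switchable via `SVMConfig.standardize`).

PLSR picks its latent dimension by leave-one-out RMSECV up to
min(20, n − 2, p, rank) — the ceiling is clipped to the numerical rank
with a warning.  The LOOCV is exact but computed efficiently: one PLS fit
per fold at the maximal dimension, with the nested smaller models read off
by truncating the rotation/loading matrices (valid because PLS components
are extracted sequentially; verified against per-dimension refits).

Metrics on the prediction set: RMSEP; R² = 1 − SSres/SStot (not squared
correlation, so it can go negative for a model worse than the mean);
RPD = SD(reference, n−1)/RMSEP, reported as +inf for a perfect fit and an
error for a constant reference.

## The synthetic cohort

The generator emulates a 183-sample cohort (84 paddy, 57 red, 42 seashore
saline) over 200 bands on 975–1645 nm.  Per sample:

* **Spectrum** (% reflectance): class baseline + class slope − Gaussian
  water trough (centre 1400 nm, σ 45 nm) − TN · class absorptivity ·
  Gaussian nitrogen/organics feature (centre ≈ 1000–1010 nm, σ 35 nm),
  clipped to [0, 100].  Class baselines are 48/44/34 % — seashore saline
  lowest, matching its stronger surface scattering.  Within-class
  variability: Gaussian jitter on baseline (SD 4 %), slope (SD 1.8) and
  trough depth (SD 2.5), a smooth correlated spectral nuisance (SD 1.2 %,
  100 nm correlation length; a stand-in for particle-size and drift
  effects) and i.i.d. band noise (SD 0.3 %).
* **TN** uniform per class: paddy 0.088–0.312 %, red 0.056–0.262 %,
  saline 0.038–0.205 % (pooled span 0.038–0.312 %).  Absorptivities
  70/55/85 % per % TN and slightly shifted feature centres per class make
  the TN–spectrum relationship heterogeneous across soil types — the
  condition under which local calibration should win.
* **ROI stack** (50 × 50 × 200): one spatially correlated Gaussian field
  per sample — white noise smoothed with a class-specific kernel (2.0 /
  3.5 / 7.0 px, ×exp(N(0, 0.2)) per-sample jitter) and normalised to unit
  variance — shared across bands and scaled by each band's reflectance
  (surface roughness is wavelength-coherent), at relative amplitude 3 %.
  Longer correlation length ⇒ smoother image ⇒ higher GLCM
  energy/homogeneity and lower contrast/entropy; saline is the smoothest
  in this sense and hence the most texture-distinct class.

Everything is driven by `numpy.random.default_rng(seed)`; identical
configuration and seed reproduce the dataset bit for bit.  Stacks are
reconstructed on demand from the stored per-sample field, keeping the
in-memory dataset a few MB.

Defaults were chosen so the cohort sits in the qualitative regime the
analysis is designed for — no single modality classifies perfectly
(effective wavelengths ≈ 85–90 %, texture ≈ 80–90 %, fused higher on
median), and local TN calibration beats the pooled model on median.  The
key ingredients are the high-dimensional smooth spectral nuisance (without
it a 200-band SVM separates the classes exactly and fusion has nothing to
add) and its 100 nm correlation length, long enough to be distinguishable
from the sharper 35 nm nitrogen feature so TN stays recoverable.

**What the generator does not emulate:** radiative-transfer physics,
moisture/particle-size confounders beyond the stated noise terms,
instrument stray light or wavelength miscalibration, nonlinear
scatter-analyte interactions, and spatially non-stationary texture.
Passing tests therefore establish that the pipeline is correct and that
the qualitative orderings hold under the stated statistical structure —
not that real soils will reproduce any particular accuracy.

## Test and verification scale

Oracle-equivalence checks run exhaustively on small instances (SPA vs QR
re-factorisation up to 12 × 8 over all start bands; LOOCV vs per-fold
refits at 12 × 3).  The study-scale stochastic checks run the full
183-sample, 200-band, 50 × 50-ROI pipeline over 10 seeds for the
classification ordering and the local-vs-general comparison, and 5 seeds
for the parity control in which all classes share one TN–spectrum model;
these sizes give stable medians while keeping the default test run to a
few minutes.  The local-vs-general assertion is made on the full-spectrum
models: the effective-wavelength variant re-runs SPA inside each
28–56-sample class, and that selection noise empirically swamps the scope
effect (a real limitation of per-class wavelength selection at these
sample sizes, checked only to stay within a 1.33× parity band of the
general model).

## Known limitations

* SPA with a category-code response (classification-mode selection)
  inherits the ordinal-regression caveat above.
* The F-test degrees-of-freedom convention (n, n) is one reasonable
  reading; others (e.g. n − m − 1) shift the selected size by a band or
  two on flat curves.
* GLCM statistics at 64 levels on 50 × 50 ROIs are count-sparse; energy
  and entropy are biased for very rough textures (mitigated, not removed,
  by direction averaging).
* Per-class EW selection below ~50 calibration samples is noisy; prefer
  the full-spectrum PLSR, or pooled selection, at that scale.
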