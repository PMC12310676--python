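# Methods

## Overview

The package re-creates, at desk scale, a satellite-simulation analysis for
canopy nitrogen estimation in apple orchards.  Because the underlying field
data (canopy hyperspectra plus Kjeldahl nitrogen for 100 samples in each of
three phenological stages) are not publicly deposited, the pipeline runs on
a synthetic canopy generator whose nitrogen → spectrum coupling is known by
construction.  Passing tests therefore demonstrate that each analysis stage
recovers structure that is genuinely present — not that the field study's
absolute accuracies are reproduced.

## Synthetic canopy generator

**Nitrogen.**  Per stage, nitrogen is drawn from a truncated normal on
[2.0, 3.9] mg·g⁻¹ with sd 0.30 and stage means 3.04 (NGS), 2.82 (NSS),
2.60 (ASS).  The sd is chosen so ±3 sd roughly spans the reported range
2.02–3.83 mg·g⁻¹.  Truncation biases a truncated normal's mean away from
its location parameter (up to ≈0.017 mg·g⁻¹ for ASS, whose mean sits
closest to the lower bound), so the generator solves for the pre-truncation
location that makes the post-truncation mean equal the configured stage
mean exactly (`brentq` on the truncated-normal mean, cached per parameter
set).

**Chlorophyll link.**  A chlorophyll index is linear in nitrogen
(slope 15, intercept −10, additive unit-sd noise, floored at 0), the
simplest monotone coupling consistent with nitrogen being a chlorophyll
constituent.  Typical values land in ≈20–48.

**Spectrum model.**  Each spectrum on the 350–2500 nm 1-nm grid (2151
points) is a parametric curve, not a radiative-transfer model:

- visible baseline 0.12 × (1 + ε), ε ~ N(0, 0.04) per sample — a
  nitrogen-independent nuisance mimicking illumination/background drift;
- two gaussian chlorophyll absorption wells at 450 nm (depth ≤ 0.075) and
  670 nm (depth ≤ 0.085) whose depths saturate as 1 − e^(−chl/8).  The
  e-folding of 8 puts canopy-level chlorophyll deep into saturation, as in
  closed canopies, so visible reflectance carries only a weak residual
  nitrogen signal;
- a logistic red edge (width 12 nm) whose inflection sits at
  700 + 0.6·chl nm (clamped at 748 nm) — the unsaturated, nitrogen-driven
  feature.  Red-edge band reflectance responds strongly to nitrogen
  through this shift;
- a near-infrared plateau at the stage amplitude (0.52 / 0.47 / 0.42 for
  NGS / NSS / ASS, encoding the observed seasonal decline in canopy
  brightness) times a per-sample lognormal structure factor
  (log-sd 0.06) independent of nitrogen — canopy-architecture variance;
- fixed water-absorption wells at 1450 and 1940 nm and a mild linear
  decline beyond 1000 nm;
- additive gaussian noise (default sd 0.004 reflectance) and a final clip
  to [0, 1].

This geometry is what makes the study's qualitative findings recoverable:
normalized differences between red-edge and NIR bands cancel the shared
structure factor and isolate the red-edge shift, so red-edge/NIR pairs
out-correlate visible–visible pairs; sensors without red-edge bands
(Landsat-8) are left with the saturated visible signal and rank below
Sentinel-2/GF-6.  The saturation scale and red-edge gain were fixed once,
when the generator was designed, to place the planted signal where the
emulated study locates it.

What the generator does **not** emulate: leaf biochemistry beyond
chlorophyll (water, dry matter, carotenoids), bidirectional/illumination
effects, soil background, instrument splice artifacts, and any covariance
between nitrogen and canopy structure.  Conclusions about real field data
cannot be read off the synthetic accuracy numbers.

**Seeding.**  All randomness derives from one user seed via
`numpy.random.SeedSequence([seed, stage_index, purpose, ...])` sub-keys;
identical calls are bit-reproducible and distinct purposes never share a
stream.  Derived integer seeds handed to scikit-learn are reduced mod 2³¹.

## Preprocessing

Field protocols only state that spectra are smoothed; the package uses a
Savitzky–Golay filter, window 15 points, polynomial order 3 — the community
default for ASD canopy spectra — and clips the output to [0, 1].  The
choice is a documented default, not an inference about any particular
field protocol; it is testable through polynomial preservation (degree ≤ 3
curves pass through unchanged away from the boundary).  Idempotence is not
claimed.

## Sensor simulation

A band reflectance is the SRF-weighted mean
∫s(λ)ρ(λ)dλ / ∫s(λ)dλ by the trapezoidal rule on the native 1-nm grid
(uniform and fine relative to all band widths).  Range-defined sensors
(Landsat-8, GF-6) get boxcar responses over their published limits;
Sentinel-2 publishes band centers, so its responses are synthesized
gaussians exp(−4 ln2 (λ−c)²/fwhm²), truncated below 1e-4, with editable
FWHM defaults in the bundled JSON configs (15 nm for the red-edge bands,
nominal instrument bandwidths elsewhere).  True response curves exist only
as plots in the emulated study, so SRF shape is configuration, not code.

The VNIR filter keeps boxcar bands wholly inside 400–1000 nm plus the
433–453 nm coastal band, and center-defined bands with centers inside
400–1000 nm — reproducing the 5 / 10 / 8 retained band counts (the GF-6
purple-edge band and the Sentinel-2 945 nm water-vapor band are retained
by these rules).

## Band-pair screening

For every unordered band pair (earlier band first in sensor order) the
normalized difference (ρᵢ−ρⱼ)/(ρᵢ+ρⱼ) is correlated with nitrogen using
the standard square-rooted Pearson denominator.  Selection is by |r| with
signed r retained; ties break to the first pair in band order.  Samples
with a zero-sum denominator are excluded pairwise from that pair's
correlation and counted; a pair with fewer than three defined samples or a
zero-variance index is skipped.

## PLSR

NIPALS with autoscaled X (center, unit sd with ddof=1) and centered y;
deflation after each component; coefficients back-transformed through
B = W(PᵀW)⁻¹q.  With a single response the power iteration converges in
one pass; the loop (tol 1e-10, ≤500 iterations) is retained defensively.
Default component count is min(3, #bands in the combination), keeping
combination comparisons uniform across sensors; it is exposed as a
parameter.  Combination reports use training-set R² (the single-R²
convention of combination screening tables); validation R² is available by
splitting upstream.  Zero-variance predictors raise an error naming the
band (with a 1e-12-relative tolerance so numerically constant columns are
caught).  The test suite checks NIPALS against ordinary least squares at
full components, against simple regression with one predictor, and against
an independent PLS implementation.

## Estimation models

60/40 train/validation split, drawn uniformly without replacement under
the run seed; one split per stage is shared by all sensors and models so
sensor comparisons are paired.  Predictors are standardized with
training-split statistics only.

- **SVM**: RBF-kernel ε-SVR (ε = 0.1); C ∈ {0.1, 1, 10, 100} and kernel
  width γ ∈ {0.01, 0.1, 1} selected by 5-fold cross-validated grid search
  on the training set.  The small fixed grid keeps runs deterministic and
  desk-scale.
- **BPNN**: one hidden layer of 2·B+1 logistic units (B = band count),
  linear output, Adam backpropagation, learning rate 0.01, ≤2000 epochs,
  early stopping on a 20% internal holdout with patience 50, seeded.

R² defaults to 1 − SSres/SStot; the explained-variance ratio
Σ(ŷ−ȳ)²/Σ(y−ȳ)² is available as `mode="eq3"` (it coincides with the
default for least-squares fits with intercept but can exceed 1 for biased
nonlinear predictors, which is why it is not the default).  RMSE is
√(Σ(y−ŷ)²/n), in mg·g⁻¹.

## Pipeline and reporting

`run_pipeline` executes generate → smooth → resample → screen → PLSR
ablation → train from one JSON config and one seed, writing every
intermediate CSV and a manifest with a config hash and per-file SHA-256
checksums; reruns under the same config are bit-identical (CSV floats are
written as %.17g and read with round-trip precision precisely to make
checksum comparison meaningful).  The run summary averages SVM training
and validation R²/RMSE arithmetically over the phenological stages per
sensor — the aggregation used to rank sensors.

## Problem sizes

Defaults are the emulated study's sizes: 100 samples per stage, 2151
wavelengths, 60/40 splits.  Distribution-level checks use 10,000 nitrogen
draws; oracle equivalences run on dozens of small random problems;
Monte-Carlo structure-recovery checks use 10 seeds at n = 100 per stage
with per-wavelength noise disabled, which isolates the planted signal from
sampling noise.

## Known limitations

- The spectrum model is phenomenological; it cannot say anything about
  absolute estimation accuracy on real canopies.
- Gaussian SRFs are an idealization of real instrument response curves;
  agency-published SRFs can be dropped in via the JSON configs.
- The BPNN depends on scikit-learn's MLP internals; determinism is
  guaranteed only for a fixed library version.
- The stage named ASS is treated as one stage throughout, whether labelled
  "autumn shoot-growing" or "autumn shoot stop-growing" — the two names
  are taken as synonyms.
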