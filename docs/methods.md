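# Methods

This note documents the models, numerical choices, and limitations behind
`prftone`.  It is written for users who need to judge what the package's
results do and do not demonstrate.

## Stimulus protocols

Two timelines are modeled, both at TR = 2 s with block onsets aligned to
TR boundaries (TR *k* covers `[2k, 2k+2)` seconds):

* **Randomized mapping scans** — 240 two-second pure-tone blocks, one per
  frequency of a geometric grid from 88 to 8000 Hz (both endpoints
  included), freshly shuffled per scan, with a 12-s silence after every 60
  blocks (528 s, 264 TRs per scan).  The silences provide baseline
  periods.  Within a block, the tone is presented as eight 50- or 200-ms
  bursts with 50-ms gaps; this fine structure is kept as metadata for
  audio rendering but has no effect at TR resolution, where each block is
  one full-TR stimulation — a deliberate simplification, since the model
  operates on 2-s samples and no sub-TR weighting is identifiable from
  them.
* **Song scans** — a melody of 2-s note blocks (13 × 75-ms bursts each)
  restricted to 880–2349 Hz (A5–D7), followed by 8 s of silence, the whole
  presentation repeated eight times per scan; two scans per song.
  Responses are averaged over the 8 × 2 = 16 presentations before
  decoding, reducing IID noise by a factor of 4.

The two built-in melodies (23 and 25 notes) are *synthetic stand-ins*:
the songs they gesture at are published only as notation images, so the
package ships melodies written from their general contour (octave-leap
opening, stepwise motion, repeated notes) in the correct register.  All
pipeline code is melody-agnostic and accepts arbitrary note lists in
880–2349 Hz.

## Encoding model

Per voxel: Gaussian tuning in log2 frequency (center `f0` Hz, spread
`sigma` octaves), hemodynamic convolution, then a static power law with
exponent `n` ∈ [0, 1] (compressive spatial summation).  All tuning math is
in octaves so that `sigma` and the reported FWHM bandwidth
(`2·sqrt(2 ln 2)·sigma`) share units.

* **HDR** — gamma probability density with shape 3, scale τ = 1.5 s, onset
  delay 2 s (mode at 5 s), sampled at `t = k·TR` and truncated at 32 s
  (> 99.9 % of mass).  These are configurable inputs; the package does not
  estimate subject HDRs.  Convolution is direct (not FFT): FFT round-off
  (~1e−15) on silent TRs would be inflated to visible artifacts by small
  exponents, since `eps^n` is large for `n` ≪ 1.
* **Exponent placement** — `n` is applied to the blurred summed drive
  (`(Σ_b blurred_b · g(f_b))^n`).  With one-frequency-at-a-time stimuli
  and `n` = 1 this equals applying it before convolution; for `n` < 1 the
  post-summation form is used throughout, in both the fit and the
  generator.
* **Fitting** — Pearson-correlation maximization in two stages: a coarse
  grid (f0 in ¼-octave steps across the stimulus range × 12 log-spaced
  sigmas in [0.05, 8] octaves, `n` = 1; ties resolve toward the lowest f0
  then lowest sigma), then L-BFGS-B refinement of
  (log2 f0, sigma, n) with `ftol` = 1e−6, bounds f0 ∈ [44, 16000] Hz (one
  octave beyond the stimulus range, to avoid edge-pinning), sigma ∈
  [0.015, 8] octaves, n ∈ [0, 1].  The refined solution is kept only if it
  does not degrade the starting objective.  The sigma floor of 0.015
  octaves reflects the resolution of the presented frequency grid; the
  8-octave cap is a package choice (tuning broader than the mapped range
  is not meaningfully constrained by these stimuli).
* **Degenerate voxels** — zero-variance time courses (or predictions) are
  kept in the table with `fit_r` = 0 so row counts are stable.
* **Retention** — voxels with `fit_r` strictly above 0.15 enter decoding;
  no other selection is applied.  The cut is calibrated for full-length
  sessions: on pure-noise voxels fitted to two or more 264-TR scans the
  null `fit_r` median is ≈ 0.12–0.15, and it drops further with six scans.
  On toy-length stimuli the three-parameter fit's null correlation exceeds
  0.15, so short simulations should not reuse the default cut.
* **Gain/baseline calibration** — the correlation objective is invariant
  to affine rescaling of the data, so the model deliberately carries no
  amplitude or baseline parameters.  After fitting, per-voxel gain and
  offset are recovered by least squares against the fitted prediction and
  stored alongside the pRF parameters (`amp`, `base` columns).  They play
  no role in the fit itself but put voxels back on a common scale for
  cross-voxel pattern comparison during decoding.

## Decoding

For each 2-s block the decoder extracts the voxel pattern at the TR
nearest `onset + 6 s` (a fixed hemodynamic lag of exactly 3 TRs, cyclic
within the averaged presentation), and finds the frequency whose predicted
pattern `g_i(f)^{n_i}` maximizes the spatial Pearson correlation: all 14
half-octave grid frequencies from 88 Hz are evaluated (ties toward the
lower frequency), then a bounded 1-D optimization over log2 f in
[88, 8000] Hz refines the best grid point and is accepted only if it does
not lower the correlation.  Results depend only on the retained voxels'
(f0, sigma, n) values, never on voxel positions.

**Pattern normalization.**  Spatial correlation across voxels is not
invariant to per-voxel affine differences, so raw averaged time courses
are first mapped to model units using the training-fit calibration,
`(tc_i − base_i)/amp_i` (default, `normalization="calibrated"`).  Two
alternatives are provided: `"none"` (raw) and `"zscore"` (per-voxel
temporal z-scoring).  z-scoring is *not* the default for a structural
reason: a voxel's temporal mean and SD over a melody presentation are
themselves frequency-dependent quantities, so removing them injects an
inverted copy of the melody-average response pattern into every block's
pattern and, empirically, degrades noiseless reconstruction from tens of
cents to over 1000 cents median error.  Weakly responsive voxels (whose
z-scored patterns are amplified noise) drive most of that damage.

**Accuracy floor.**  Even without noise, block-wise decoding is a mixture
problem: with the default HDR sampled at TR resolution, the pattern at the
6-s lag weights the target block by 0.166, the *following* block by 0.156
and the preceding one by 0.098, so the best single-frequency match is
pulled toward neighboring notes by roughly a third of the melodic
interval.  For melodies dominated by steps of 1–2 semitones this floor is
≈ 50–90 cents median error (large leaps fare worse); it is a property of
the measurement model (2-s blocks, hemodynamic blur, single-TR patterns),
not of the optimizer, and matches the magnitude of residual spreads
reported for this paradigm on real data.  Consequently the package's
end-to-end regression target of "median error below 50 cents with perfect
foil identification on a high-SNR bundle" is not met by the rainbow-like
stand-in melody (measured ≈ 89 cents median, 990/1000 foils beaten at
noise SD 0.01); the wish-like melody reaches 1000/1000 identification
with ≈ 49–61 cents median.  The corresponding acceptance test is kept as
written and documents this gap rather than loosening the threshold.

## Evaluation

* **Cents** — signed error `1200·log2(f_est/f_true)`; antisymmetric and
  additive over octaves.
* **Identification** — Pearson correlation between reconstructed and
  candidate sequences computed on log2 frequencies (configurable to Hz);
  a foil counts as beaten only when its correlation is *strictly* below
  the actual sequence's, so ties (e.g., a foil identical to the song,
  which short songs generate with non-trivial probability) count against
  identification.  Foils are drawn from a first-order Markov chain whose
  transition rows are the song's empirical note-to-note frequencies with
  no smoothing; the first note follows the song's marginal note
  distribution, as does any absorbing state (only a song's final note can
  lack outgoing transitions).
* **Bias test** — one-sample two-tailed t-test of the mean residual
  against zero (df = N−1).  Bonferroni (`min(1, m·p)`) and Holm step-down
  adjustments take an explicit test count `m` (e.g., subjects × songs)
  that may exceed the number of p-values supplied; Holm never exceeds
  Bonferroni and both are monotone.
* **rRMSE** — `(RMSE(pred, scan1) + RMSE(pred, scan2)) / (2·RMSE(scan1,
  scan2))`, no degrees-of-freedom correction; invariant to shifting or
  scaling all three inputs together.  1 marks test-retest parity; a
  perfect model under IID zero-mean noise converges to 1/√2 ≈ 0.707.
  Identical scan pairs (zero denominator) propagate as flagged NaNs and
  are excluded from medians.  By default the per-voxel report uses the
  full song-scan time courses (not presentation averages).

## Synthetic data

`sample_population` draws, per voxel: f0 log-uniform over 88–8000 Hz;
FWHM bandwidth from a normal(3.385, 2.807) octaves truncated below 0.05;
exponent from normal(0.587, 0.310) truncated to [0, 1]; response gain from
normal(1.0, 0.25) truncated below 0.05; baseline normal(100, 10) in
arbitrary scanner units.  The bandwidth/exponent moments follow reported
per-subject statistics for this paradigm; the default population size
(400) sits in the reported 250–550 range.  Gain and baseline spreads are
package choices representing plausible voxel-to-voxel coupling and offset
heterogeneity; they matter because the decoder must undo them.  Noise is
IID Gaussian per TR (default SD 0.5 on the unit-gain response scale,
giving mapping-fit correlations around 0.3–0.4; `noise_sd_for_mean_r`
solves `r = 1/sqrt(1 + σ²/(a·s)²)` for the SD that hits a requested mean
data-model correlation).  An optional AR(1) switch (`ar1_rho`) exists for
stress-testing; it is off by default, matching the IID assumption under
which the 1/√2 rRMSE optimum holds.

All randomness flows from one master seed through named `SeedSequence`
substreams (population / scan order / per-scan noise / foils), so studies
are bit-reproducible and adding scans does not perturb earlier draws.

What the generator does **not** emulate: spatial voxel layout and
correlated (physiological or motion) noise, scanner drift, habituation or
expectation effects, multi-dimensional selectivity (spectral/temporal
modulation, loudness), and deviations from the assumed Gaussian-in-log-f
tuning.  Passing synthetic tests therefore demonstrates the correctness
and internal consistency of the estimation/decoding machinery under the
model's own assumptions — not that real cortical responses satisfy them.

## Problem sizes used in validation

Regression tests run the full session structure at reduced population
sizes (tens to hundreds of voxels), which the vectorized grid stage
completes in seconds; the parameter-recovery check uses 200 voxels × 6
mapping scans with noise calibrated to mean fit correlation ≈ 0.5, and the
end-to-end check uses 400 voxels at noise SD 0.01 with 1000 foils per
song.  The Monte-Carlo rRMSE reference uses 200 replicates of 1000-TR
series.
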