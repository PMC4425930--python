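# Methods

This note documents the models, parameter choices and numerical decisions
behind `wcms`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The measurement model the simulator emulates

A linear-mode whole-cell profile over m/z 3,000–30,000 (uniform 1 Da grid by
default) is rendered as

```
x(m) = B(m) + Σ_k A_k · exp(−(m − c_k − d(m))² / 2σ_k²) + ε(m),   clipped at 0
```

* **Baseline** `B(m) = a₁·exp(−m/τ₁) + a₂·exp(−m/τ₂)` (defaults a₁=150,
  τ₁=1200 Da, a₂=12, τ₂=9000 Da): a steep low-mass chemical/matrix
  background plus a shallow tail, the shape seen in raw whole-cell spectra.
* **Peaks** are symmetric Gaussians with σ = 0.0008·m/z, mimicking
  linear-mode resolution. Apex amplitude is the product of a base
  intensity, the group multiplier, and log-normal gains (below). Base
  intensities are drawn so that the apex SNR on the variance-stabilised
  scale is log-uniform in [5, 70] — every planted peak is in principle
  detectable at an SNR-3 cut, with a realistic tail near the limit. The
  required amplitude is solved per position against the local baseline, so
  low-mass peaks need larger amplitudes for the same SNR.
* **Noise** is Gaussian with sd = 0.25·√(signal + 1): shot-noise-like
  heteroscedasticity. This is precisely the model under which the
  pipeline's square-root transform stabilises variance (sqrt-scale noise
  sd ≈ 0.25/2 = 0.125, nearly constant).
* **Mass-axis warp** `d(m)` is a per-spectrum quadratic polynomial whose
  maximum displacement is bounded by 3 Da — smooth enough for LOWESS to
  recover, large enough to defeat naive binning if uncorrected.
* **Variability model** (all log-normal, multiplicative):
  whole-spectrum donor gain (sd 0.15) and spot/replicate gain (sd 0.10) —
  the gain variation that motivates median normalization; per-(donor,
  protein) *biological* abundance variation (sd 0.20), of which half the
  variance is shared between a donor's two cell preparations and half is
  cell-type specific (distinct cell types have correlated but not
  identical proteomes); and per-spot peak jitter (sd 0.05).
* **Planted effects.** The default panel holds 80 common peaks (including
  bright calibrant-like peaks at m/z 4078.8 and 14019.1), 12 population
  markers (multiplier U(2.5, 10) in one population, spanning the 2.5–10×
  range of reported discriminatory peaks), 8 condition markers (U(2.5, 6)
  under LPS and/or PPD in one or both populations), and one +80 Da shift
  pair whose transfer fraction is 0 everywhere except 0.5 under the
  CD16+/LPS analog group. In addition, every common peak receives a
  population "fingerprint" factor, log-normal with sd 0.25 and median
  exactly 1 per population: distinct cell types differ modestly across
  most of their fingerprint, not only at a handful of markers. Without
  this broad structure no correlation-matrix PC1 could plausibly reach the
  ~40 % variance and clean class separation that whole-cell fingerprinting
  of distinct cell types exhibits. The factors are median-centred because
  a *global* intensity ratio between populations is unidentifiable under
  per-spectrum median normalization — planting one would plant an
  unmeasurable quantity.

Determinism: every spectrum is a pure function of (seed, donor, population,
condition, replicate); independent RNG streams are derived from named
`SeedSequence` keys, so panel, warps, gains and noise are all reproducible
and the truth object records everything needed for scoring.

Not modelled (out of scope): analyte-suppression competition, isotopic
structure, matrix adduct chemistry, non-uniform TOF sampling grids (all
operations take explicit m/z axes, so the uniform grid is only a simulator
convenience).

## Pipeline parameters and their rationale

| parameter | default | units | rationale |
|---|---|---|---|
| sg_window / sg_polyorder | 21 / 3 | points | ~2–8σ of peak widths on a 1 Da grid; preserves degree-≤3 structure exactly |
| tophat_half_window | 75 | Da | ≫ peak widths (removes nothing narrower), ≪ baseline decay scales |
| noise_window | 500 | Da | long enough for a stable MAD, short enough to track heteroscedasticity |
| snr_threshold | 3 | — | the workflow's stated retention rule |
| anchor_masses | 4078.8, 14019.1 | Da | conserved peaks used for affine pre-alignment |
| match_tolerance_rel | 0.002 | — | 2000 ppm, the linear-mode mass-accuracy scale; used for anchors, reference building, merging and binning |
| lowess_span / iterations | 0.67 / 3 | — | smooth warp recovery with robustness to mismatched peaks |
| align_min_frequency | 0.9 | — | reference peaks must recur in ≥ 90 % of spectra |
| min_frequency (matrix filter) | 0.9 | — | a feature must be detected in ≥ 90 % of samples of at least one (population, condition) group |
| alpha / fc_threshold | 0.001 / 2 | — | the discriminatory-peak rule |
| delta / pair_tolerance | 80 / 1.0 | Da | nominal phosphorylation/sulfation shift; printed pair masses differ by 80.04–80.1, so "exactly 80" is treated as nominal |

All are config-exposed; none of the window sizes is prescribed by the
emulated workflow itself, so they are package choices suited to ~1 Da grids
over 3–30 kDa.

## Numerical decisions

* **Noise scale.** The MAD noise estimate is taken on the *unsmoothed*
  baseline-corrected residual. Estimating it on the smoothed trace would
  understate the physical noise ~5× (smoothing removes most of the
  high-frequency variance) and turn the SNR-3 cut into an SNR-0.6 cut,
  flooding the peak lists with noise maxima. The estimate is evaluated at
  window centres spaced window/8 apart and interpolated; a strictly
  positive floor (relative to the signal maximum) keeps degenerate spectra
  finite.
* **Intensity scale.** Detection runs on the sqrt scale; reported peak
  amplitudes are back-transformed to the acquisition scale as
  `(h + b)² − b²` (exact inversion above the estimated baseline). Group
  intensity ratios on this scale recover planted fold-changes; on the sqrt
  scale a 2.5× effect would read as 1.58× and the FC > 2 rule would lose
  its meaning.
* **Normalization bookkeeping.** The median normalizer m is computed from
  provisional (pre-alignment) peak amplitudes; the retained sqrt-scale
  signal, baseline and noise are divided by √m so that linear-scale
  amplitudes derived later are consistently divided by m. The median of
  provisional peak intensities is exactly 1 afterwards.
* **Detection details.** Strict local maxima within ±5 grid points; maxima
  closer than the matching tolerance are merged (broad high-mass peak tops
  carry several noise maxima); apex m/z is refined by an intensity-weighted
  centroid over ± half the matching tolerance, which reduces apex
  localisation error on wide peaks from ~2–3 Da to well under 1 Da.
* **Edge handling.** Savitzky–Golay edges use a polynomial fit over the
  first/last window; morphology uses edge replication, which for flat
  structuring elements is identical to truncated-window min/max (verified
  against the brute-force oracle).
* **Warp monotonicity.** The fitted LOWESS warp is applied as a shift
  field; if the warped axis ever fails strict monotonicity it is repaired
  by cumulative maximum plus a vanishing ramp. Spectra matching fewer than
  5 reference peaks keep their anchor-based affine mapping (recorded in
  provenance).
* **ANOVA conventions.** Balanced designs use closed-form sums of squares,
  vectorised across features; with one observation per cell the additive
  model is fitted and the interaction serves as residual (the
  per-population condition analysis is a condition × donor block design).
  Unbalanced designs fall back to per-feature type-II least squares via
  statsmodels with a logged warning. Zero-variance features get F = 0,
  p = 1 by convention and can never be hits. Post-tests use the pooled
  residual variance; Bonferroni multiplies by the family size (population
  contrasts per condition, or pairwise condition contrasts per
  population). Fold-change ratios are stabilised with ε = 10⁻⁶ × the
  median positive matrix value.
* **Replicate averaging.** Matrix cells average over the replicates in
  which the peak was detected (n_detected is reported); zero-imputing all
  misses would bias planted fold-changes downward. The zero-imputing
  variant is available behind `average="all"`.
* **PCA.** Columns standardized with the n−1 standard deviation;
  zero-variance features dropped; deterministic sign convention (largest
  loading positive). Variance fractions are eigenvalues of the correlation
  matrix divided by the number of retained features.

## Problem sizes used by the tests and the reproduction script

The acceptance battery runs 20 independent default studies (2 populations ×
3 conditions × 8 donors × 4 replicates = 192 spectra each, ~100 planted
peaks) — enough replication for the stochastic checks while keeping the
whole suite comfortably fast; statistical calibration uses an all-null
matrix of 1000 features at the same 48-sample layout. Oracle equivalences
run on 50 random spectra (TopHat) and fixed random instances (Savitzky–
Golay, PCA, ANOVA toy).

## What passing tests show — and what they do not

The synthetic tests demonstrate that the implementation is faithful (oracle
equivalence, exact bookkeeping in noise-free runs) and that under the
modelled conditions the chain recovers what was planted: ≥ 95 % of
confidently planted peaks, fold-changes with mean bias within ±5 %, every
strong population marker, the planted shift pair uniquely, and PC1 class
separation. They do **not** show that real whole-cell spectra satisfy the
model: real peak shapes are asymmetric, suppression couples analyte
intensities, baselines vary with matrix crystallisation, and biological
variability is not log-normal. Two method-level caveats carry over to real
data: per-spectrum median normalization leaves a residual sample-coherent
scale error of a few per cent (visible as a common-mode PCA component when
biological variability is small), and cross-population fold-changes inherit
a seed-level offset of up to ~10 % from the composition of the detected-
peak median — both are properties of the published workflow, not of this
implementation.

## Known limitations

Gap-filling (re-integrating raw signal at bins missed by detection) is not
implemented; centroid-mode mzXML, vendor raw formats and mzML writing are
out of scope; the ANOVA assumes independent samples (donor pairing across
populations is not modelled as a random effect); Bonferroni is the only
multiplicity correction, as in the emulated analysis.
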