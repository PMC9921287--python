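# Methods

## Scope and data model

`leafspec` models the relationship between Vis–NIR leaf reflectance
(400–1000 nm, 462 bands at ~1.3 nm spacing — the grid of a 12-bit
line-scanner imaging spectrometer) and foliar nutrient concentrations
measured by reference chemistry. Spectra travel as an `n × 462` matrix of
relative reflectance on a [0, 1] scale (an optional ×10,000 integer display
convention is provided); nutrients as a per-sample table in % of dry mass
(N, P, K, Ca) or mg/kg (Al, B, Cu, Fe, Mg, Mn, Na, S, Zn).

## Reflectance calibration

`R = (R0 − D)/(W − D)` per band, with dark frame `D` and a white reference
`W` (~99% reflective). References are frame-averaged per-band vectors by
default; per-pixel arrays are accepted for per-pixel calibration (which of
the two an instrument vendor uses varies, so both are supported). Pixels are
calibrated first and ROI-averaged second; under per-band references the two
orders commute exactly, so the choice is a convention, not a model decision.
Negative corrected values are retained, not clipped: scatter-correcting
transforms (MSC, SNV) assume the full signal, and clipping would bias them.
Values outside [−0.05, 1.5] trigger a warning only.

## Preprocessing transforms

The transform grid is: raw, SNV, MSC, area normalisation, de-trending
(orders 2–4) and OSC. The literature names these without fixing every
detail; the canonical choices here are:

- **SNV** — per-spectrum centring and scaling to unit sample sd (n−1).
  Stand-alone, not followed by de-trending.
- **MSC** — per-spectrum OLS against the *mean calibration spectrum*;
  output `(x − a)/b`. Test spectra are corrected against the calibration
  reference, never refit.
- **Area normalisation** — each spectrum divided by the sum of its values
  (rectangle rule on the uniform grid); rows sum to 1.
- **De-trending** — least-squares polynomial in wavelength subtracted per
  spectrum; stand-alone (not SNV-detrend). Wavelengths are rescaled to
  [−1, 1] before fitting so that orders up to 4 on 462 points stay well
  conditioned. De-trending is an orthogonal projection, hence idempotent.
- **OSC** — Wold's original algorithm: per component, take the dominant
  principal score of the (deflated) calibration matrix, orthogonalise it
  against the centred response, solve for the weight vector reproducing it,
  iterate to convergence (tolerance 1e-10, max 500 iterations), then remove
  the rank-one term. The orthogonalisation uses the projection of `y` onto
  the column space of `X`: scores are constrained only by the reachable part
  of the response, and this keeps the removed score exactly representable as
  `Xw`, so the filter acts identically on calibration and new data. Sign
  convention: the largest-magnitude loading element is positive. Default one
  component.

### Leakage control

MSC and OSC learn state from calibration data. Applied to the test set they
use only calibration-fitted state. Inside leave-one-out CV they are *refit
on every fold*: OSC's weights are estimated under an orthogonality
constraint involving the calibration `y`, so a single fit on all calibration
samples leaks each held-out response into its own fold — measured effect: CV
R² ≈ 1.0 for every nutrient while test R² collapses, and OSC spuriously wins
every model selection. With nested refits the transform grid behaves
normally. Row-local stateless transforms (SNV, normalisation, de-trending)
are applied once; folding them would change nothing.

## PLSR and model selection

Single-response NIPALS: per component `w = Xᵀy/‖Xᵀy‖`, `t = Xw`,
`p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, deflate `X` and `y`. Columns are centred but
not variance-scaled (bands share units; scatter is the transforms' job).
Accumulated coefficients `b = W(PᵀW)⁻¹q` reproduce the deflation-form
predictions to ~1e-9 relative; both forms are kept and cross-checked.
Requesting more components than the centred rank raises an error naming the
attainable maximum.

Leave-one-out CV refits everything per fold, including the centring. The LV
count is selected at minimum PRESS over 1..15 candidates (15 caps the search;
ties break to the smaller count for parsimony). If a fold exhausts its rank
early, its prediction is held constant for larger counts — an exact fit
cannot improve. PRESS, `RMSE_CV = √(PRESS/n)` and `R²_CV` come from the
held-out predictions at the selected LV.

Across transforms the winner is ranked by R²_CV (descending), with ties
within 1e-6 broken by RMSE_CV, then R²_C, then fewer LVs. R²_CV is primary
because it is the generalisation measure; "highest R² and lowest RMSE" is
not otherwise a total order.

## Screening and splitting

Hotelling's T² uses the first `k = 5` principal components by default
(configurable; `None` selects min(5, components covering 95% of variance)),
each squared score normalised by its component variance, against the
threshold `k(n−1)/(n−k) · F(1−α; k, n−k)`, α = 0.05. Screening runs once per
surface data set, before splitting; survivors are not re-screened.

The 80/20 split draws `round(0.8·n)` calibration samples uniformly at
random. Mean equality per nutrient is checked with Welch's t-test (the
safer unequal-variance default); if any p ≤ 0.05 the split is redrawn with
an incremented seed, up to 100 times, and the accepted split's p-values are
recorded. A constant nutrient yields p = 1 (zero mean difference). One split
is fixed per nutrient × surface so the transform comparison is paired.

## Test-set evaluation

`R²_P` uses the test set's own mean in the total sum of squares (the
standard external-validation convention; a flag switches to the calibration
mean). `RPD = SD_test/RMSE_P` with the n−1 standard deviation, banded
*excellent* (> 2.0), *good* ([1.4, 2.0]), *below good* (< 1.4). No finer
split below 1.4 is attempted — prose distinctions between "moderate" and
"low" models track R²_P, for which no RPD threshold exists, so the report
carries R²_P alongside the band instead of inventing one. Within a report
row `RPD × RMSE_P` equals the test SD to 1e-9 by construction, checked in
tests.

## Synthetic data generator

The generator is phenomenological, not radiative-transfer: its job is to
emulate the *statistical* structure the analysis assumes, with a known
ground truth.

- **Baselines.** The adaxial baseline combines a 0.08 floor, a green peak
  (560 nm), small secondary peaks (600/640 nm), chlorophyll-a and blue
  absorption wells (670/445 nm) and a red-edge sigmoid rising to a ~0.46 NIR
  plateau. The abaxial baseline adds a difference term
  `(0.035·exp(−((λ−567)/110)²) + 0.012) · tanh((735−λ)/8)`: positive below
  the single 735 nm crossing with its maximum near 567 nm, negative in the
  NIR — the empirical ordering of real leaf surfaces.
- **Latent components.** Four: chlorophyll-well depth, green-peak height,
  red-edge shift, NIR amplitude, with amplitudes 0.02–0.03 reflectance units
  per unit standard-normal score.
- **Scatter and noise.** Per-sample multiplicative scatter (sd 0.05 of the
  baseline), additive offset (sd 0.01), per-band noise (sd 0.002). Real-leaf
  scatter magnitudes are not published for this instrument class; these
  defaults are config-exposed and chosen so scatter dominates band noise, as
  in practice.
- **Nutrients.** Each nutrient is `mean + signal_sd·(wᵀz/‖w‖) + ε`,
  `ε ~ N(0, noise_sd)`, clipped to its physiological [min, max];
  `signal_sd² + noise_sd² = sd²`, so the analytic ceiling on prediction is
  `R² = 1 − (noise_sd/sd)²`. Ranges, means and SDs follow published
  descriptive statistics for macadamia '816' leaves (e.g. N 1.03–2.89%,
  mean 1.68, sd 0.41). Noise fractions are set so the R² ceilings echo the
  relative predictability reported for leaf spectra (N, P, K, Ca, Cu, Zn
  well coupled; Al, B, Fe, Na mostly spectrally silent). Clipping (rather
  than resampling) slightly thins the tails and biases realised variance
  downward for narrow-ranged nutrients — documented, accepted for
  simplicity.
- **Cubes.** `raw = D + R·(W − D) + noise` inside the ROI against a dark
  tray background; dark frame ~2% of the 12-bit full scale with a slow
  per-band ripple, white frame 99%. Zero-noise round trips through the
  calibration module recover the input spectrum to float precision.

What passing tests on this generator do **not** show: robustness to
non-linear pigment saturation, moisture/structural covariates, instrument
drift, stray light, or nutrient–spectrum relationships that are not affine
in a low-dimensional latent space. Results on real leaves depend on those.

## Problem sizes and numerics

Default runs use n = 120 samples per surface (96/24 split) and candidate
LVs up to 15; property tests use 20×50 to 200×462 problems — sizes at which
the brute-force oracles (naive LOO refit loops, normal-equation solves,
exhaustive ranking comparisons) are exact and fast. Degenerate inputs fail
loudly and early: constant spectra (SNV), zero-area rows, constant
responses, `W = D` bands, empty ROIs, rank-exhausted component requests.
Fitted transforms and models serialise to JSON text and reload bit-exactly.

## Known limitations

- PRESS-minimum LV selection on small calibration sets is noisy; a
  one-standard-error rule would pick smaller models but is not what the
  standard workflow does.
- The Hotelling screen is spectral-only; no leverage/residual screening in
  the response dimension.
- PLS1 only (one nutrient at a time); no PLS2, interval-PLS or variable
  selection — the full 400–1000 nm range is always used.
- The generator's surface difference is deterministic; real adaxial/abaxial
  contrasts vary by leaf age and cultivar.
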