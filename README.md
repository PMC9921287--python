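# leafspec

Chemometrics for laboratory Vis–NIR hyperspectral imaging of tree leaves:
from raw line-scanner cubes to cross-validated predictions of foliar
nutrient concentrations.

Foliar nutrient analysis normally takes days of wet chemistry (combustion,
acid digestion, ICP-AES). Hyperspectral imaging of leaves in the 400–1000 nm
range offers a rapid proxy: mineral nutrients do not absorb in Vis–NIR
themselves, but they bind to organic macromolecules (chlorophyll and other
pigments, structural proteins) whose absorption features the camera does
see. `leafspec` implements the standard modelling chain used for this kind
of data — and ships a synthetic leaf-spectra generator so the whole pipeline
runs and is tested end to end without any instrument data.

## The method

1. **Reflectance calibration.** Raw digital numbers `R0` are corrected
   against a dark frame `D` and a white-reference frame `W`
   (`R = (R0 − D)/(W − D)` per band), then averaged over a leaf
   region-of-interest mask.
2. **Outlier screening.** Hotelling's T² on the first principal-component
   scores, thresholded at `k(n−1)/(n−k) · F(1−α; k, n−k)` with α = 0.05.
3. **Split.** Random ~80/20 calibration/test split; a Welch t-test per
   nutrient confirms the two sets have indistinguishable means (p > 0.05),
   redrawing otherwise.
4. **Preprocessing grid.** Raw, SNV, MSC, area normalisation, de-trending
   (polynomial orders 2–4) and Wold-style OSC. Transforms that learn state
   from calibration data (MSC reference, OSC weights) are refit inside every
   cross-validation fold — OSC fitted once on all calibration samples would
   leak the held-out response and inflate R²_CV.
5. **PLSR.** Single-response NIPALS partial least squares; the number of
   latent variables (LV) is chosen at the minimum PRESS
   (`PRESS = Σᵢ(ŷᵢ − yᵢ)²` over leave-one-out predictions).
6. **Evaluation.** `R² = 1 − SS_res/SS_tot`, `RMSE = √(Σ(ŷᵢ−yᵢ)²/n)` on
   calibration, cross-validation and the untouched test set, plus
   `RPD = SD_test/RMSE_test`, banded as *excellent* (> 2.0), *good*
   ([1.4, 2.0]) or *below good*.

The synthetic generator draws leaf spectra as a surface-specific baseline
(green peak near 560 nm, chlorophyll well near 670 nm, red edge, NIR
plateau) plus latent physiological components, multiplicative/additive
scatter and band noise; nutrient concentrations are affine in the same
latent scores plus noise. The two surfaces behave like real leaves: the
abaxial (lower) side reflects more below ~730 nm (largest gap near 567 nm),
the adaxial (upper) side more in the NIR.

## Worked example

```bash
leafspec simulate --n 120 --surface adaxial --seed 7 --out-dir demo
leafspec fit --spectra demo/spectra_adaxial.csv \
             --nutrients demo/nutrients_adaxial.csv \
             --nutrient P --surface adaxial --transform msc --max-lv 15 --seed 7
```

prints

```
P (adaxial, MSC): LV=4 R2_C=0.816 RMSE_C=0.01383 R2_CV=0.643 RMSE_CV=0.01927
R2_P=0.665 RMSE_P=0.02343 RPD=1.76 (good)
```

Reading: after MSC scatter correction, leave-one-out PRESS selected 4 latent
variables; the model explains 82% of calibration variance and 64% under
cross-validation; on the 24 held-out samples it predicts phosphorus
concentration (% of dry mass) with RMSE 0.023 and an RPD of 1.76 — a "good"
model by the usual banding. The same chain is available from Python:

```python
import leafspec as ls

spectra, nutrients = ls.generate_spectra(120, "adaxial", seed=7)
split = ls.split_calibration_test(spectra.sample_ids, nutrients, seed=7)
X = spectra.subset(split.calibration_ids).reflectance
y = nutrients.values_for("P", split.calibration_ids)
cv = ls.loo_cv(X, y, max_lv=15)
model = ls.fit_plsr(X, y, cv.selected_lv)
```

`leafspec run --out-dir results` executes the full grid (13 nutrients ×
2 surfaces × 8 transforms) and writes a report with one row per nutrient and
surface, the winning transform, LV count, all metrics and the RPD band.

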