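# canopy2sat

Satellite-band simulation and canopy nitrogen estimation from hyperspectral
reflectance, built around the question: *which open-access satellite —
Landsat-8, Sentinel-2 or GF-6 — is best suited to monitoring nitrogen in
apple-orchard canopies, and which bands carry the signal?*

Field campaigns answer this by measuring canopy reflectance (350–2500 nm at
1 nm with an ASD-type spectroradiometer) and leaf nitrogen (Kjeldahl,
mg·g⁻¹) across phenological stages, then convolving the hyperspectra
through each sensor's spectral response functions (SRFs) to obtain
simulated satellite band reflectances free of atmospheric effects.  This
package implements that entire analysis as a seeded, testable pipeline over
a synthetic canopy generator with a *known* nitrogen → spectrum coupling,
so every downstream step can be validated against planted ground truth:

1. **`synth`** — seeded canopy spectral libraries: 100 samples per stage
   (new-shoot-growing NGS, new-shoot-stop-growing NSS, autumn-shoot ASS),
   truncated-normal nitrogen with stage means 3.04 / 2.82 / 2.60 mg·g⁻¹,
   chlorophyll-driven absorption wells and a chlorophyll-shifted red edge.
2. **`preprocess`** — Savitzky–Golay smoothing of the 1-nm spectra.
3. **`sensors`** — SRF convolution
   ρ_band = ∫s(λ)ρ(λ)dλ / ∫s(λ)dλ into each sensor's
   visible–near-infrared bands (5 Landsat-8, 10 Sentinel-2, 8 GF-6).
4. **`screening`** — every band pair's normalized difference
   (ρᵢ−ρⱼ)/(ρᵢ+ρⱼ) correlated with nitrogen (Pearson r).
5. **`plsr`** — from-scratch NIPALS partial least squares regression for
   band-combination and band-removal (ablation) studies.
6. **`models`** — SVM (RBF, cross-validated grid) and BPNN
   (single-hidden-layer backpropagation) nitrogen estimators on a 60/40
   train/validation split, scored with R² and RMSE.

## Worked example

The numbered drivers under `analysis/` run the whole study and write their
tables under `results/`:

```sh
python analysis/01_simulate_libraries.py --seed 1
python analysis/02_simulate_sensors.py
python analysis/03_screen_band_pairs.py
python analysis/04_plsr_band_combinations.py
python analysis/05_train_estimators.py --seed 1
python analysis/06_summarize.py
```

Step 03 prints the winning normalized-difference pair per sensor × stage;
with the default seed the winners sit in the red-edge/near-infrared region
for the red-edge-capable sensors — exactly the signal the generator plants:

```
gf6       NSS: best pair (NIR, RE2)  r = +0.958
landsat8  NSS: best pair (Blue, Red)  r = +0.632
sentinel2 NSS: best pair (RE2, NIR1)  r = -0.962
```

Step 06 aggregates the SVM accuracy over the three stages.  Sensors with
dedicated red-edge bands resolve the nitrogen-driven red-edge shift that
Landsat-8's broad bands average away:

```
   sensor  mean_r2_training  mean_rmse_training  mean_r2_validation  mean_rmse_validation
sentinel2             0.945               0.064               0.933                 0.073
      gf6             0.943               0.065               0.933                 0.074
 landsat8             0.782               0.127               0.670                 0.164
```

R² is the fraction of nitrogen variance explained; RMSE is in mg·g⁻¹ of
leaf nitrogen.  (Absolute values reflect the synthetic generator's noise
level, not field accuracy; the *ranking* and the red-edge finding are the
reproduced structure.)

The same workflow is available as a CLI (`canopy2sat generate | smooth |
resample | screen | plsr-screen | train | report`, or `canopy2sat run
--config cfg.json` for an end-to-end seeded run with a checksummed
manifest).

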