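# seedspectra

Multispectral image analysis for seed quality classification.

Seed lots are heterogeneous: storage and ageing silently degrade viability and
vigor, and the damage is invisible to the eye. Multispectral reflectance
imaging makes it measurable — a petri dish of seeds is imaged at 20 narrow LED
bands from the UV (375 nm) to the shortwave NIR (970 nm), and each seed's mean
reflectance spectrum becomes a 20-value fingerprint of its physicochemical
state. Aged seeds reflect less in the 505–780 nm range and more above 780 nm
than fresh seeds, which is enough signal for a linear discriminant model to
sort them.

`seedspectra` implements the full analysis for seed physiologists and
phenotyping engineers:

- **Cube handling** — `H×W×20` reflectance cubes with wavelength-addressed
  band access, stored as multi-page TIFF + JSON wavelength manifest.
- **Segmentation** — seeds are bright at 780 nm, so the mask is a single
  threshold of that band (`mask = 1` where `I > T`, Otsu or explicit `T`),
  followed by 8-connected blob labelling with a speck filter.
- **Spectral extraction** — per-seed mean spectra collected into the seeds ×
  bands matrix `X`, with dummy-coded class vector `Y` and stratified
  train/validation splitting.
- **Chemometrics** — PCA exploration, and from-scratch LDA: class centroids
  `μ_k`, pooled within-class covariance `Σ`, squared Mahalanobis distances
  `d_k(x) = (x−μ_k)ᵀ Σ⁻¹ (x−μ_k)`, posteriors ∝ `π_k · exp(−d_k/2)`,
  leave-one-out cross-validation, confusion matrices and the overall correct
  classification `OCC = 100 · correct / total`.
- **Classification images** — the fitted discriminant applied to every seed
  pixel, refolded into a colour map (blue background, green non-aged, red
  aged) that makes invisible ageing visible.
- **Synthetic scenes** — a generator of labelled 25-seed petri-dish cubes and
  seed-lot label tables (ageing / germinated / Early–Medium–Dead vigor /
  Normal–Abnormal seedling classes) so every stage can be validated against
  exact ground truth.

## Worked example

Render a mixed dish of 25 seeds (13 fresh, 12 aged 96 h), segment it, extract
signatures and cross-validate a discriminant model:

```python
import seedspectra as ss

base = ss.default_seed_profile()
aged = ss.make_ageing_profiles(base)["AA96"]
profiles = {
    "Non-aged": base,
    "Aged": ss.ClassSpectralProfile("Aged", aged.mean_reflectance,
                                    base.seed_level_sd, base.pixel_noise_sd),
}
spec = ss.SceneSpec(image_size=(700, 700), n_seeds=25,
                    seed_classes=("Non-aged", "Aged") * 12 + ("Non-aged",),
                    rng_seed=0)
cube, truth = ss.render_scene(spec, profiles)

mask = ss.threshold_band(cube.band(780.0), 0.4)
blobs = ss.label_blobs(mask)
X = ss.extract_mean_spectra(cube, blobs)
y = ss.LabelVector.from_labels(X.seed_ids, truth.classes_for_blobs(blobs),
                               ["Non-aged", "Aged"])
print(f"segmented {len(blobs)} seeds at T = {mask.threshold_used}")

result = ss.LinearDiscriminant.from_spectra(X, y).fit()
print(result.summary())
print(ss.loocv(X, y.codes, class_names=y.class_names).summary())
```

Output:

```
segmented 25 seeds at T = 0.4
Linear discriminant model
============================================================
Observations: 25    Bands: 20    Classes: 2
Priors (proportional): Non-aged=0.5200, Aged=0.4800
Regularization lambda: 1e-06
Class counts: Non-aged=13, Aged=12
Classification report
==============================================
                Non-aged        Aged  % correct
    Non-aged          13           0     100.00
        Aged           0          12     100.00
Overall correct classification: 100.00%  (n = 25)
```

All 25 seeds are recovered by the 780 nm threshold, and leave-one-out
cross-validation separates aged from non-aged seeds perfectly — the synthetic
spectral contrast (≈ 8 % visible-band depression after 96 h of ageing) is far
larger than the between-seed variability. A pixel-wise map of the same dish is
one more line:

```python
ss.save_map_png(ss.classify_pixels(cube, mask, result), "map.png")
```

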