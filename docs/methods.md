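# Methods

This note documents the models and procedures implemented in `seedspectra`,
the assumptions behind them, and the choices made where the design was open.

## The measurement model

A multispectral cube is an `H × W × B` stack of reflectance planes acquired at
`B = 20` LED bands with centres at 375, 405, 435, 450, 470, 505, 525, 570,
590, 630, 645, 660, 700, 780, 850, 870, 890, 910, 940 and 970 nm. Reflectance
is dimensionless (calibrated against a white standard), stored in 32-bit
floating point, and may slightly exceed 1 on specular points; values are
accepted up to a ceiling of 1.5. Band addressing is by wavelength (±0.5 nm),
never by raw index: vendor conventions count bands 1-based (the 780 nm plane
is "band 14") while arrays are 0-based, and wavelength addressing removes the
ambiguity. The default pixel pitch is 0.0432 mm.

No native instrument format is documented publicly, so cubes serialise to an
open stack: one grayscale TIFF page per band plus a JSON manifest
`{"wavelengths_nm": [...], "pixel_size_mm": ...}`. The round trip is lossless
at stored precision.

## Segmentation

Seeds are bright at 780 nm against an opaque dish/background, so the seed
mask is a threshold of that single band:

    mask(i,j) = 1  if I(i,j,780nm) > T,   0 otherwise

(the mask is 0 *at* the threshold; foreground is strictly above it, which
makes re-thresholding a binary mask with the same T idempotent). `T` may be
given explicitly or selected by Otsu's method. Otsu assumes an essentially
bimodal histogram; on three-population scenes (dark surround, mid-grey dish,
bright seeds) it will split the two largest populations, so a dish-aware or
explicit threshold should be used there — the pipeline defaults expose both.

Blobs are 8-connected components of the mask; components below
`min_area_px = 50` pixels (≈ 0.09 mm² at the default pitch, far below any
seed) are discarded as specks. Blob ids run 1..K in raster order of each
component's first pixel, so ordering is deterministic and stable under
filtering. Touching seeds are *not* separated (no watershed): dishes are
assumed to have spaced seeds, which the synthetic generator guarantees by
construction; this is a documented limitation for crowded real dishes.
Morphological opening is available (`opening_radius`) but off by default.

## Spectral signatures

A seed's signature is the arithmetic mean of its pixels per band — a
20-vector per seed, assembled into the seeds × bands matrix `X` with the
dummy-coded response `Y` (0/1 for two-class, 0/1/2 for three-class
groupings). Signatures stay on the raw reflectance scale: no SNV, derivative
or autoscaling is applied (a `preprocess` hook exists and defaults to the
identity), because the discriminant models are designed for raw spectra.

Train/validation splitting is stratified-random per class:
`round(fraction · n_class)` seeds go to validation (at least one when the
fraction is positive), reproducibly from one integer seed. Published splits
whose per-class counts do not fall on a single rounding rule can be
reproduced exactly via explicit per-class `validation_counts`.

## Discriminant model

Classical LDA in distance form. Class `k` is summarised by its centroid
`μ_k`; all classes share the pooled within-class covariance

    Σ = ( Σ_k Σ_{i∈k} (x_i − μ_k)(x_i − μ_k)ᵀ ) / (n − K).

A spectrum `x` is scored by squared Mahalanobis distance
`d_k(x) = (x−μ_k)ᵀ Σ⁻¹ (x−μ_k)`, discriminant score
`g_k = −d_k/2 + ln π_k`, and posterior membership probability
`p_k = exp(g_k) / Σ_j exp(g_j)` (computed with max-subtraction for numerical
stability). Assignment is the posterior argmax, which under equal priors is
the minimum-distance rule and for two classes is the "membership probability
above 0.5" rule; exact posterior ties go to the lowest class index.

Open choices, resolved as follows:

- **Priors** default to training class frequencies (`proportional`), which is
  the natural choice for heavily unbalanced seed lots; an `equal` switch
  exists.
- **Regularisation**: `Σ ← Σ + λ·(trace(Σ)/B)·I` with `λ = 1e−6` by default,
  keeping the 20-band covariance invertible for small classes; `λ = 0` is
  allowed when the data permit (a non-invertible covariance is then an
  error). When the within-class scatter is exactly zero (perfectly noise-free
  synthetic data) the trace scale degenerates, and the ridge falls back to
  unit scale so the model reduces gracefully to a nearest-centroid rule.
- **Display rounding** is half-up to two decimals and applies only to report
  output; all internal comparisons use full precision.

Accuracy is tabulated from the K×K confusion matrix (rows = true class):
per-class accuracy `100 · diagonal / row sum` and overall correct
classification `OCC = 100 · trace / total`. Leave-one-out cross-validation
refits the model `n` times, each time classifying only the held-out seed;
every class therefore needs at least three members. The refits are literal
(no downdating shortcut): at `n` in the hundreds and `B = 20` the cost is
negligible, and the implementation stays transparently equal to its
definition.

Discriminant factors for score plots solve the generalized eigenproblem
`S_b v = λ Σ v` with `S_b` the between-class scatter of the centroids; at
most `K−1` factors carry variance and their explained-variance percentages
are normalised over those `K−1`. For `K = 2` a single factor is returned with
a warning.

PCA uses the sample covariance (n−1 denominator) of the column-centred
matrix; explained-variance percentages are relative to total variance and sum
to 100 over a full-rank decomposition.

## Pixel-wise classification images

The cube is unfolded row-major to an `(H·W) × B` matrix of pixel spectra; the
fitted discriminant classifies the rows inside the seed mask, and the verdict
vector is refolded to an `H × W` label plane (0 = background, 1..K = model
classes). Background is handled by masking, not by a trained background
class — background pixels never pass through the model. The default colour
map is blue background, green "Non-aged", red "Aged", with a fixed cycle of
distinct colours for further classes; per-pixel posteriors can optionally be
kept as a confidence layer. Unfold order is immaterial to correctness (the
refold inverts it) and is fixed row-major for reproducibility.

## Synthetic scenes and labels

The generator emulates the acquisition conditions the pipeline assumes: 25-seed
petri dishes at the 20-band grid. Defaults render 700 × 700 px scenes with
seed radii 18–28 px — the acquisition geometry (2056 × 2056 px, whole-dish
field) scaled down ~3× so a scene renders in well under a second; all spatial
statistics (areas in px) scale accordingly.

- **Geometry**: the dish is a centred disk (radius 0.45·min(H,W)); seeds are
  filled axis-aligned ellipses with eccentricity drawn from [1.0, 1.6]
  (seed shape is otherwise unspecified; ellipses suffice to exercise
  segmentation), placed by rejection sampling with a non-overlap margin and a
  bounded retry budget. An optional dark hilum patch exists for stress
  testing and is off by default.
- **Spectra**: the baseline signature mimics a cream-coloured legume seed
  coat (reflectance rising from 0.08 in the UV to ≈ 0.6 in the NIR, dipping
  at the 940/970 nm lipid/water bands). Ageing for `d` hours scales the
  505–780 nm bands by `1 − (d/24)·vis_drop` and the >780 nm bands by
  `1 + (d/24)·nir_rise` (defaults 0.02 and 0.01 per 24 h), leaving 375–470 nm
  untouched — reproducing, by construction, the observed ageing contrast:
  darker visible, brighter NIR, ordered by severity. Each seed draws a
  per-band Gaussian offset (`seed_level_sd`, default 0.01) and each pixel
  adds Gaussian noise (`pixel_noise_sd`, default 0.02).
- **Labels**: a lot of `n` seeds (default 501: 100 non-aged, 401 aged across
  AA24–AA96) draws germination Bernoulli per ageing class (defaults 0.97 →
  0.35, non-increasing with ageing), germination-start times from a
  log-normal (median 36 h for fresh seeds, multiplicative delay 1.12 per
  24 h of ageing, σ = 0.3 on the log scale — chosen for right skew; draws are
  truncated to the 72 h scoring window by resampling), and abnormal-seedling
  Bernoulli among germinated seeds (0.05 → 0.50). Class rules are invariant:
  Early ⇔ germinated within 48 h, Medium ⇔ within 72 h, Dead ⇔ never;
  non-germinated seeds are always Abnormal (dead is lumped with abnormal).
- **Determinism**: all randomness flows from one integer seed through a
  single generator; equal specs give bitwise-identical scenes and lots.

What the generator does *not* emulate: optical blur and specular highlights,
seed-coat texture and the cowpea hilum (by default), illumination gradients,
touching seeds, and any real biochemical covariance structure between bands —
its band noise is independent. Passing tests therefore demonstrate that the
pipeline's machinery is correct and recovers planted structure under the
stated noise model; they do not certify classification accuracy on real
dishes.

## Problem sizes and numerical checks

The test suite validates each stage against independent oracles on small
fixtures: flood-fill labelling (scipy.ndimage) for blobs, brute-force
sum/divide for signatures, term-by-term scatter accumulation and full
Gaussian-density posteriors for LDA, literal per-fold refits (scikit-learn)
for LOOCV, dense covariance eigendecomposition for PCA, and a per-pixel
double loop for classification images. End-to-end recovery runs two
700×700×20 dishes of 25 seeds each (the aged/non-aged contrast ≈ 5× the
seed-level SD), requiring exact 25-blob recovery per dish and ≥ 95 %
cross-validated accuracy; the whole suite runs in a few seconds on one CPU.

Known limitations: no watershed separation of touching seeds; Otsu
thresholding assumes near-bimodal histograms; the label model's germination
window is capped at 72 h (later germination is not representable in the
three-class vigor taxonomy); LDA assumes shared within-class covariance and
will underperform when classes differ mainly in dispersion.
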