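# Methods

## The estimation problem

The target is zeaxanthin content (g/kg dry exocarp) of ripe chili peppers,
measured optically from mean reflectance spectra at 19 bands between 365 and
970 nm.  The obstacle is multicollinearity at the absorber level: capsanthin,
the dominant red pigment, absorbs in nearly the same blue window as
zeaxanthin (profile correlation > 0.94 across the instrument grid), so the
reflectance data alone identify the *sum* of the two contributions well but
their split only weakly.  The package's central model treats the measured
capsanthin and total carotenoid contents as auxiliary inputs: conditioned on
capsanthin, the blue-band signal attributable to zeaxanthin becomes (nearly)
noise-limited rather than confound-limited.

## Synthetic populations

All tests and examples run on synthetic populations, because the original
159-sample dataset is external.  The generator composes:

- **Absorbance profiles** — unit-peak Gaussians: zeaxanthin (460 nm, σ 35),
  capsanthin (475 nm, σ 40), chlorophyll (450 and 670 nm, σ 25), and a
  pooled carotenoid background (520 nm, σ 30).  Reflectance is
  `clip(baseline − Σ content·amplitude·profile + noise, floor, 1)` with a
  logistic baseline rising from ≈ 0.15 (UV) to ≈ 0.75 (NIR plateau) and an
  instrument dark-level floor of 0.02 so band ratios stay defined.
- **Zeaxanthin content** — a 3:1 mixture of two lognormal clusters
  (genetic background): high accumulators ~ lognormal(median 1.70 g/kg,
  σ 0.85), low accumulators ~ lognormal(median 0.32, σ 0.30), truncated to
  0.237–6.64 g/kg by resampling.  The four cluster parameters were
  calibrated jointly, once, against two targets: a calibration-subset
  (n = 126) coefficient of variation of ≈ 88 %, and genuinely separable
  clusters (optimal-threshold accuracy ≈ 0.93).  A single shared σ cannot
  satisfy both under the truncation: scans showed separable single-σ designs
  cap near CV 78 %, and CV-matching single-σ designs leave the clusters
  unresolvable even by the Bayes rule.
- **Capsanthin** — constructed with a target Pearson correlation to
  zeaxanthin (default ρ = 0.8) by mixing the standardized target with fresh
  Gaussian noise and rescaling to the target's moments.
- **Total carotenoids** — zeaxanthin + capsanthin + a positive remainder
  ~ |N(8, 4)| g/kg.  The remainder dominates the total on purpose: in red
  exocarp, total carotenoids are mostly pigments other than zeaxanthin, so
  chemistry alone must NOT pinpoint the target.  (An early draft used a
  small remainder; that made the chemical-only regressor nearly perfect,
  contradicting both pigment composition and the ablation structure this
  generator exists to emulate.)
- **Noise** — i.i.d. Gaussian, SD 0.003 reflectance units per band.  Mean
  spectra are averages over ~10⁵ ROI pixels, so a small per-band SD is the
  realistic regime.  This value matters scientifically: at SD ≳ 0.01 the
  capsanthin-subtraction channel is noise-limited and fusing chemistry gains
  nothing a linear model can measure; at 0.003 the fusion advantage
  (≈ +0.1–0.15 test R²) emerges from decoupling alone.
- **Amplitudes** — zeaxanthin 0.012, capsanthin 0.030, chlorophyll 0.05,
  background 0.002 absorbance per (g/kg).  Chosen once via a linear-oracle
  design study (ridge regression at the 126/33 study scale) so that the
  spectral-only model lands near R² ≈ 0.8 and the fused input set near 0.95,
  the regime the analysis pipeline is designed for.

What the generator does **not** emulate: instrument line shapes and stray
light, scattering/particle-size effects, nonlinear absorbance saturation
(Kubelka–Munk behavior), wavelength-correlated noise, and any real genetic
covariance beyond the two-cluster location/scale structure.  Passing tests
therefore show that the pipeline recovers the *designed* statistical
structure, not that it would hit the same accuracy numbers on real powder
spectra.

## Preprocessing

Spectra are transformed by a single-scale continuous wavelet transform
(Mexican hat, scale 3 band-widths, symmetric boundary extension) — a standard
derivative-like filter that removes smooth baseline structure exactly (the
sampled kernel is forced to zero sum, so additive offsets map to zero).  The
wavelet shape is sampled from PyWavelets; the convolution itself is explicit
so the boundary rule is controlled and testable against a brute-force oracle.
Min-max normalization statistics (per band, and per chemical feature) are fit
on the calibration set only and applied unchanged to held-out data; constant
features map to 0.5; held-out values are not clipped.  Band selection is
available on either raw or preprocessed spectra; the shipped pipeline selects
on raw reflectance, where the band correlation matrix is well conditioned
enough for Bartlett's determinant.

## Dataset splitting

Stratified 8:2 splitting (126 calibration / 33 test at n = 159) draws test
samples proportionally from 5 quantile strata of the response, with
largest-remainder rounding to hit the exact test size.  Split validity is
assessed with a two-sample Kolmogorov–Smirnov test
between calibration and test response distributions (asymptotic p-value);
the suite requires p > 0.05 in ≥ 90 % of 50 seeds.  LOOCV fold indices over
the calibration set are recorded in the split assignment.

## Band selection

Applicability is gated by the overall KMO measure (anti-image partial
correlations from the inverse correlation matrix; a ridge of 1e−8 is applied
only when cond(R) > 1e10, so well-conditioned inputs are computed exactly)
and Bartlett's sphericity test.  PCA runs on standardized data (correlation
matrix); component signs are fixed by making each component's
largest-magnitude loading positive.  The per-sample composite score is the
explained-variance-ratio-weighted mean of the leading component scores
(k = 2 by default).  Backward stepwise regression of that score on the band
reflectances removes the least significant predictor while its p-value
exceeds `alpha_remove` (default 0.05; an optional `max_bands` cap keeps
pruning the least significant predictor for parity experiments at a fixed
band count).  The composite-score weighting and the p-value-based removal
rule are the standard constructions; neither is uniquely determined by the
source description.

## Models

All networks use kernel-3 "same" convolutions, width-2 max pooling, global
average pooling (GAP), and ReLU activations:

- **Spectral-only CNN** (2 177 trainable parameters):
  conv(1→16) → pool → conv(16→32) → GAP → dense(32→16) → dense(16→1).
- **Fusion model** (3 929): the same encoder up to the 32-d GAP vector; a
  chemical branch dense(2→16) → dense(16→8); concat(40) → dense(40→48) →
  batch normalization → dense(48→1).  The feature-replacement variant is
  architecturally identical with (CRI, total carotenoids) as chemical
  inputs; CRI is always computed from the full-band raw spectra since the
  RGB windows are measured regardless of which bands feed the encoder.
- **Chemical-only regressor**: the chemical branch plus an 8→1 head.

The layer plan is pinned by the two parameter budgets above; GAP is what
makes the encoder band-count-independent.  Because the counts are the
architecture's contract, the networks are implemented directly in numpy with
explicit backpropagation (verified against finite differences); this also
exposes the gradient at the second convolution's feature map, which 1-D
Grad-CAM needs.  Training is full-batch Adam on MSE (defaults lr 1e−3,
≤ 2000 epochs, patience 100) with early stopping on an internal held-out
fraction (default 15 %) and best-weight restoration; fixed seeds give
bit-identical runs.  The multi-seed property suites use epochs 1500,
lr 5e−3, patience 150, validation fraction 0.2 — settings chosen for
training reliability at suite scale (the slower default schedule
occasionally under-trains within the patience window on the bimodal
response).  Baselines (random forest, MLP, PLS) are scikit-learn wrappers.
Validation metrics can be computed on pooled LOOCV predictions.

## Evaluation

R² = 1 − SS_res/SS_tot (the explained-variance form Σ(ŷ−ȳ)²/Σ(y−ȳ)² is also
provided; the two coincide only for least-squares fits).  RMSE divides by n;
RPD = SD(y)/RMSE with the sample SD (ddof = 1), so RPD·RMSE = SD(y) exactly;
RPD ≥ 3 is flagged "reliable", 2.4–3 "general", below "poor".  The paired
t-test of predictions against measurements uses df = n − 2, the convention
under which the two-sided 1 % critical value at n = 33 is 2.744 (df = 32
would give 2.738).

## Interpretability

The ablation suite trains five input configurations under identical
hyperparameters: spectra only; the two chemical indicators only; spectra +
two standard-normal noise features; spectra + chemistry perturbed by 5 %
relative multiplicative Gaussian noise (relative, because contents span an
order of magnitude); spectra + authentic chemistry.  The sensitivity sweep
replaces measured capsanthin by a synthetic proxy with correlation ρ to the
true zeaxanthin (grid 0.2–0.95), retrains the fusion model from scratch per
ρ, and records test R².  Grad-CAM weights are positional averages of the
output gradient at the second convolution's post-ReLU feature map; the
rectified weighted activation sum is linearly interpolated from pooled
positions back to bands.  t-SNE (perplexity 15, PCA initialization, fixed
seed) embeds the pre-head feature vectors (32-d spectral or 40-d fused).

## Known limitations and negative results

- **Band-reduction asymmetry.**  The acceptance property "reducing 19 → 5
  selected bands hurts the fusion model less than the spectral-only model"
  does not hold under these study conditions (a minority of seeds) and is reported
  honestly as failing.  The fusion model's advantage rests on the 430–500 nm
  overlap bands (for capsanthin subtraction) plus a chlorophyll anchor near
  660–690 nm; the composite-score selector keeps variance-dominated bands
  that preserve the spectral-only sum channel instead, so the fusion model
  falls to its chemistry floor and loses more.  A hand-chosen
  overlap-plus-anchor set {450, 470, 490, 660, 690} does reproduce the
  asymmetry (fusion drop ≈ 0, spectral drop ≈ 0.05), showing the property is
  a statement about which bands a dataset's selector happens to keep, not
  about the architecture.
- **Unsupervised cluster recovery.**  With a 75/25 mixture whose only
  cluster-linked variable is the response itself, 2-means on a t-SNE
  embedding splits by mass, not by genotype (~0.65 agreement even when the
  Bayes rule reaches 0.93), so the feature-space diagnostic is tested as a
  permuted-label significance test on the between-cluster centroid distance
  (p < 0.01 in 10/10 seeds) rather than as an 80 %-agreement clustering.
- **Grad-CAM suppression.**  Under the decoupling mechanism the fusion model
  actively *uses* the overlap bands (that is where the conditional zeaxanthin
  signal lives), so the overlap-region saliency is not systematically lower
  than the spectral-only model's; the saliency test instead checks that
  attention concentrates in the pigment-active window (405–690 nm) rather
  than the information-free NIR bands.
- With ρ = 0 chemistry the fusion model does not degrade toward the
  spectral-only model — it stays far above it, because measured capsanthin
  explains the spectral interference regardless of its correlation with the
  target.  The "fusion cannot hurt" property is therefore one-sided.
- Reported accuracies on synthetic data are not estimates of accuracy on
  real pepper spectra; only the qualitative orderings are designed to carry
  over.

## Problem sizes

The shipped suites train ≈ 130 networks (10 seeds × {paired models, five
ablation configurations, two band-reduced models}, 5 seeds × 4 sensitivity
points) at n = 159 with 126 training samples each, plus one n = 500 planted-
recovery fit; the whole test run takes ≈ 7 minutes on one CPU.  The
acceptance script uses 20 generator seeds and runs in seconds.
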