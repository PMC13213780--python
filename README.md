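# chilispec

Multispectral chemometrics for quantifying **zeaxanthin** in chili-pepper
(*Capsicum annuum*) exocarp from 19-band reflectance spectra (365–970 nm),
in the presence of severe spectral multicollinearity with **capsanthin**.

## The problem

Zeaxanthin and capsanthin are structurally near-identical carotenoids whose
absorption profiles overlap almost completely in the blue window
(430–500 nm).  A regression model trained on reflectance alone cannot cleanly
attribute blue-band absorption to one pigment or the other: it ends up
predicting zeaxanthin partly through its correlation with capsanthin, which
inflates variance and breaks down when the covariance structure shifts.  The
package implements a multimodal answer: feed the model the measured
capsanthin and total carotenoid contents alongside the spectra, so it can
*subtract* the interfering contribution instead of guessing it — turning a
two-pigment disentanglement problem into a conditional single-pigment
estimate.

## What's in the box

| module | contents |
|---|---|
| `chilispec.synthetic` | population generator: overlapping Gaussian absorber mixtures, truncated two-cluster lognormal zeaxanthin (0.237–6.64 g/kg, CV ≈ 88%), configurable zeaxanthin–capsanthin correlation, 3:1 genetic clusters |
| `chilispec.preprocess` | spectra/chemistry CSV I/O, single-scale continuous-wavelet preprocessing, min-max normalization with calibration statistics, stratified 8:2 splitting, two-sample KS checks, composite red index (CRI) |
| `chilispec.band_selection` | KMO + Bartlett applicability tests, PCA with variance-weighted composite scores, backward stepwise selection of characteristic wavelengths |
| `chilispec.models` | the 1-D CNN spectral regressor (2 177 trainable parameters), the chemical–spectral fusion regressor `mcsf` (3 929), its CRI feature-replacement variant `mcsf_fr`, RF/MLP/PLS baselines, full-batch Adam training with early stopping, LOOCV |
| `chilispec.evaluation` | R², RMSE, RPD (with reliability categories), paired t-test (df = n−2), report assembly |
| `chilispec.interpretability` | five-configuration ablation, chemical-correlation sensitivity sweep, 1-D Grad-CAM saliency, t-SNE feature-space diagnostics |

The two network architectures (kernel-3 convolutions, max pooling, global
average pooling, a 2→16→8 chemical branch, a 40→48 fused layer with batch
normalization) are implemented in numpy with explicit forward/backward
passes; global average pooling makes the encoder's parameter count
independent of the number of input bands, and the exact trainable-parameter
budgets (2 177 spectral-only, 3 929 fusion, an 80.5 % increase) are verified
by `count_parameters`.

## Worked example

```bash
python examples/train_fusion.py
```

prints (seed 42):

```
trainable parameters: spectral-only = 2177, fusion = 3929
model          Rt2     Rp2   RMSEp    RPD  flag
spectral     0.880   0.810   0.618   2.33  poor
mcsf         0.980   0.905   0.437   3.29  reliable
           paired t-test on the prediction set: |t|=2.145 vs t_crit=2.744 (df=31) -> no significant bias
mcsf_fr      0.952   0.790   0.649   2.22  poor
```

Reading it: on a 159-sample synthetic population split 126/33, the
spectral-only CNN reaches a prediction-set R² of 0.81 but an RPD of 2.3 —
below the ≥ 3 bar for a reliable quantitative calibration.  Adding the two
measured chemical inputs (fusion model) lifts the prediction set to
R² = 0.905 and RPD = 3.29, a reliable calibration, and the paired t-test
finds no systematic bias (|t| < t₀.₀₁ = 2.744 at df = 31).  Replacing the
measured capsanthin with the purely optical composite red index
(CRI = 0.4·R/G + 0.3·R/B + 0.2·NRGI + 0.1·RPI) costs accuracy but needs no
wet chemistry at prediction time.

The other examples follow the same pattern: `generate_dataset.py`
(population statistics and split diagnostics), `select_bands.py`
(KMO/Bartlett/PCA/stepwise screening report), `interpret.py` (ablation,
sensitivity sweep, Grad-CAM, t-SNE).

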