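# chirosense

Chemometric deconvolution of multi-modal chirality-sensing spectra.

A chromophoric probe derivatizes chiral amines / amino alcohols and induces
CD and UV responses: UV scales with each analyte's total concentration, CD
with the difference between its enantiomer concentrations (enantiomers give
exact mirror-image CD). `chirosense` simulates such measurements for
quaternary (2 analytes x 2 enantiomers) and octonary (4 x 2) mixtures across
two solvents, then recovers every enantiomer concentration — and from it the
total concentration, enantiomeric ratio (er), ee and absolute configuration —
by multivariate regression on the fused spectra.

## What is inside

| Module | Purpose |
| --- | --- |
| `chirosense.spectra_io` | Spectrum/grid types, CSV + minimal JCAMP-DX readers, resampling, dataset manifests |
| `chirosense.synthetic` | Gaussian-band component bases, linear mixing forward model, noise, campaign designs |
| `chirosense.preprocessing` | Mean centering, unit-variance scaling, hard/soft block scaling, concatenation — all invertible via `ScalingRecord` |
| `chirosense.chemometrics` | PCA (SVD), OLS, PCR, PLS2, coordinate-descent LASSO |
| `chirosense.multiblock` | Consensus MBPCA and MBPLS with block scores/loadings and per-LV block importance |
| `chirosense.model_selection` | LOOCV (preprocessing refit per fold), RMSE / averaged R², latent-variable selection |
| `chirosense.report` | er / ee / configuration derivation, univariate complementary-wavelength mode, campaign error reports |
| `chirosense.pipelines` | End-to-end fit/predict pipelines (`pcr`, `pls`, `mbpls`, `mbpca-ols`, `lasso-pcr`, `lasso-pls`) with JSON serialization |

MBPLS uses the consensus formulation whose predictions coincide exactly with
PLS2 on the concatenated, identically preprocessed matrix; that equivalence is
enforced in the test suite as a correctness oracle.

## CLI

```bash
# 1. simulate a campaign (design YAML -> spectrum CSVs + manifest)
cat > design.yaml <<EOF
design: quaternary     # or octonary
n_train: 16
n_test: 5
seed: 1
noise: {multiplicative_sd: 0.01, additive_sd_fraction: 0.003, seed: 1}
EOF
chirosense simulate --config design.yaml --out data/

# 2. fit a model on the training rows (k selected by LOOCV when omitted)
chirosense fit --manifest data/manifest.json --method pcr --scaling uv --k 4 --out model.json

# 3. predict concentrations + chirality for all samples in a manifest
chirosense predict --model model.json --manifest data/manifest.json --out predictions.json

# 4. train/test evaluation with heat-map style error bins
chirosense evaluate --manifest data/manifest.json --method mbpls --out eval

# 5. block-importance table of a fitted multiblock model
chirosense report --model model.json --out importance.csv
```

Methods: `pcr`, `pls`, `mbpls`, `mbpca-ols`, `lasso-pcr`, `lasso-pls`.
Scalings: `center`, `uv` (unit variance), `hard`, `soft` (block scaling).

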