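# ramanfda

Functional versus discrete chemometrics for Raman spectra.

Raman spectra are acquired as vectors of intensities on a fixed wavenumber
grid, and the standard classification pipeline — principal component
analysis followed by linear discriminant analysis (PCA-LDA) — treats the
grid points as independent variables. Functional data analysis (FDA)
instead models each spectrum as a smooth latent function x_i(t), fitted by
a B-spline basis expansion x_i(t) = Σₖ c_ik φ_k(t), and replaces PCA by
functional PCA (FPCA): the eigenanalysis of the sample covariance operator
v(s, t) = N⁻¹ Σᵢ x̃_i(s) x̃_i(t), whose eigenfunctions β_j satisfy
∫ v(·, t) β_j(t) dt = ρ_j β_j and are normalized by ∫ β_j² = 1. Scores are
the functional inner products f_ij = ∫ β_j x̃_i, and an LDA on the leading
scores classifies exactly as in the discrete arm.

This package provides everything needed to compare the two regimes under
controlled conditions:

- a **two-class Raman simulator** (three Gaussian bands; the "abnormal"
  class has one band shifted by Δν̃) with exact SNR control and an optional
  random smooth background, covering a 7-shift × 9-SNR study grid of 63
  datasets (200 spectra × 1024 points each);
- a **clamped B-spline basis** module (Cox–de Boor evaluation, exact Gram
  matrix by per-span Gauss quadrature);
- **least-squares functional approximation** with elbow-method selection of
  the number of basis functions K;
- **FPCA** solved exactly in coefficient space through the Gram matrix, and
  a matched-convention **discrete PCA** baseline;
- **Fisher LDA** on scores with an equal-prior pooled-covariance rule;
- a **cross-validation harness** (stratified k-fold and leave-one-batch-out)
  with strict train/test separation, mean sensitivity as the metric, and a
  Kruskal–Wallis test comparing the two arms per grid cell.

User spectra can be run through the same comparison via a plain CSV matrix
format (label column, optional batch column, one intensity column per grid
point).

## Worked example

```python
import ramanfda as rf

# the "easy" study cell: largest peak shift, high SNR, no background
spectra = rf.simulate_dataset(rf.SimulationConfig(shift=0.05, snr=30, seed=7))
folds = rf.make_folds(spectra.labels, scheme="kfold", k=10, seed=7)

for method in ("pca_lda", "fpca_lda"):
    res = rf.run_method_cv(spectra, method, n_components=50,
                           folds=folds, n_basis=190)
    print(method, f"{res.mean:.2f} +/- {res.sd:.2f}")
```

prints

```
pca_lda 1.00 +/- 0.00
fpca_lda 1.00 +/- 0.00
```

i.e. both arms separate the classes perfectly (cross-validated mean
sensitivity 1.00 with zero spread across the 10 folds) when the shifted
band is well resolved and the noise is low. At low SNR combined with a
small shift, both arms fall toward the 0.5 chance level, and in between the
functional arm tends to win because the B-spline fit suppresses point
noise. The same sweep over all 63 cells:

```
ramanfda compare --grid --seed 1 --n-components 50 --outdir results/
```

writes `grid_results.csv` with columns shift, snr, sens_pca, sd_pca,
sens_fpca, sd_fpca, diff (FPCA − PCA) and kw_p (Kruskal–Wallis p-value on
the per-fold sensitivities).

The CLI also exposes `simulate`, `simulate-grid`, `elbow`, `fit` and `run`;
see `ramanfda --help`.

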