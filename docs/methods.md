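# Methods

## The model and the two analysis regimes

A measured Raman spectrum is a vector x_i ∈ ℝᵖ of intensities on a shared
grid t₁ < … < t_p. The discrete regime analyzes these vectors directly:
PCA extracts m orthonormal loading vectors β_j maximizing the mean-square
scores under ‖β_j‖² = 1, and an LDA on the N × m score matrix separates the
classes. The functional regime first posits a smooth latent function per
spectrum, x_i(t) = Σₖ c_ik φ_k(t), estimated by least squares in a clamped
B-spline basis, and then performs the same two steps with functional
objects: the covariance *operator* replaces the covariance matrix, L²
inner products replace dot products, and the eigenfunctions β_j(t) are
normalized by ∫ β_j² = 1. Everything downstream (scores → LDA →
prediction) is shared code, so any performance difference between the arms
is attributable to the representation, not to mismatched conventions.

## Simulator

Both classes are sums of three Gaussian bands a·exp(−(t − μ)²/(2w²)) on the
normalized axis [0, 1]; the abnormal class translates one band by the peak
shift Δν̃ ≥ 0. Defaults: positions (0.25, 0.50, 0.75), widths (0.010,
0.015, 0.010), amplitudes (1.0, 0.8, 0.6), shifted band = the middle one.
These stand-in band parameters give three well-separated peaks of realistic
relative width (≈1% of the spectral range) and are fully overridable in
`SimulationConfig`; the shift values of the study grid (0.001–0.05) only
make sense on a normalized axis, which is why the simulator works on [0, 1]
with p equally spaced points including both endpoints.

Noise is i.i.d. Gaussian per point with standard deviation
σ = (maximum of the noise-free signal)/SNR, mirroring the experimental SNR
estimate implemented in `estimate_snr` (amplitude of a strong band divided
by the standard deviation of a signal-free "silent" region). The study grid
is 7 shifts × 9 SNRs ∈ {0.5, …, 100} = 63 cases of 200 spectra (100 per
class) × 1024 points.

The optional random background is a per-spectrum quadratic
b₀ + b₁t + b₂t², with coefficients drawn uniformly non-negative (hence the
polynomial is non-negative on the domain) and rescaled so its maximum is
uniform on [0.5, 2] × the tallest band amplitude. A low-order polynomial is
the conventional stand-in for a smooth Raman baseline: it is orders of
magnitude flatter than the bands (its second differences are >10× smaller
than the sharpest peak's), so it perturbs the class geometry without
introducing new sharp structure. What the simulator deliberately does *not*
emulate: cosmic-ray spikes, detector etaloning, wavenumber-calibration
errors, and Poisson/heteroscedastic shot noise. Conclusions from the test
suite therefore speak to additive-Gaussian conditions with smooth
baselines, not to every artifact of real instruments.

Randomness: one master seed per dataset; the 63-case grid derives per-case
sub-seeds via `SeedSequence(seed, spawn_key=(case_index,))`, so cases are
independent, reproducible, and order-insensitive.

## B-spline basis and functional approximation

The basis is clamped (boundary knots repeated O times) with equally spaced
interior knots; O = 4 (cubic) everywhere by default. Two conventions the
recursion leaves open are fixed as: 0/0 terms are 0 (required once knots
repeat), and the half-open support indicators are closed at the right
domain endpoint so the last grid point is representable. Knots are indexed
from 0 internally; the classical presentation indexes from t₁.

The Gram matrix W (W_kl = ∫ φ_k φ_l) is computed by a Gauss–Legendre rule
with O nodes per knot span — exact for the degree-(2O − 2) integrand — and
entries with |k − l| ≥ O are exactly zero by local support.

Coefficients minimize ‖x_i − Φc‖² via an orthogonal-decomposition solver
(LAPACK lstsq), requiring K ≤ p and a full-rank design; the explicit
normal-equations solution exists only as a test oracle. The number of
basis functions is chosen by the elbow of the pooled RMSE(K) curve: both
axes are min–max normalized to [0, 1] (raw K and RMSE are incommensurate)
and the candidate farthest from the chord between the first and last
points wins, ties to the smallest K. K is selected once per dataset, not
per spectrum. The study sweeps use K = 190 without background and K = 180
with background.

## FPCA and discrete PCA

In coefficient space the covariance operator eigenproblem becomes a K × K
symmetric eigenproblem: with centered coefficients C̃,
(1/N)·W^{1/2} C̃ᵀC̃ W^{1/2} u = ρ u, and b = W^{−1/2}u gives the
eigenfunction coefficients, W-orthonormal by construction (so ∫ β_j² = 1).
W^{±1/2} are formed symmetrically from the eigendecomposition of W with an
eigenvalue floor of 1e−12. This is exact for piecewise polynomials — no
grid discretization — and costs O(K³); a dense-grid quadrature PCA is kept
as an independent test oracle only. The sample operator of N centered
functions has rank ≤ N − 1, so at most N − 1 eigenvalues are nonzero.

Centering: the classical covariance-function formula can be read without
mean subtraction, but the variance-maximization framing presupposes
centered data, so centering is the default; `center=False` reproduces the
literal uncentered second-moment operator. The discrete arm uses the same
1/N population convention and is solved by thin SVD of the centered matrix
(contract-equivalent to the covariance eigenproblem); it is implemented in
the package rather than delegated to an external PCA so both arms share
sign conventions (each component is flipped so its largest-magnitude entry
is positive) and centering rules.

## LDA

Between-scatter B = Σ_l n_l (m_l − m)(m_l − m)ᵀ and within-scatter
W_s = Σ_l Σ_{i∈l} (x_i − m_l)(x_i − m_l)ᵀ; the within-scatter sum runs over
class members (the only dimensionally consistent reading). The L − 1
discriminant directions are the leading eigenvectors of W_s⁻¹B, computed by
Cholesky whitening of W_s followed by a symmetric eigen-solve, then scaled
to unit Euclidean norm; the bias b₀ = −Ω m̄ centers the discriminant
coordinates. A singular W_s raises with instructions to reduce the number
of components — no silent regularization — with an explicit `ridge` escape
hatch for users who want it.

Prediction uses the equal-prior linear Gaussian rule (minimal Mahalanobis
distance to the class means under the pooled within-class covariance
W_s/(N − L)), with ties broken to the lexicographically smallest label.
Equal priors fit the balanced 100/100 design; class-frequency priors are
out of scope.

## Cross-validation and comparison

Folds are stratified (class proportions preserved within one member) for
k-fold, or one fold per batch for leave-one-batch-out. Per fold, the
component model is fitted on training data only; test spectra are
projected into the training component space — for the functional arm, raw
test spectra are first converted to functions by least squares against the
*training* basis (knots fixed), since the projection step needs functional
inputs. The basis size is fixed per run rather than re-selected inside
each fold, matching a single global choice of K; per-fold elbow selection
can be done by calling `elbow_select` on each training fold explicitly.
Each fold's fitted parameters are fingerprinted (SHA-256) so leakage
audits can verify that corrupting a test fold's labels never moves the
model fitted on its complement.

Mean sensitivity is per-class recall averaged over classes (the standard
multi-class definition), averaged over folds, with the spread reported as
the standard deviation across folds. The per-cell method comparison feeds
the two arms' per-fold mean sensitivities (k + k values) to a
Kruskal–Wallis test (tie-corrected H, chi-square p with 1 df); identical
samples are reported as H = 0, p = 1. Grid sweeps record failed cells as
missing rather than aborting.

## Numerical choices and limitations

- Least squares: QR/SVD-based, never normal equations, for conditioning at
  K ≈ 190 on 1024 points.
- Elbow ties and exactly linear RMSE curves resolve to the smallest K
  (distances within 1e−12 of the maximum are treated as tied).
- Eigenvalues clipped at 0 after the symmetric solves; eigenvalue floor
  1e−12 in W^{±1/2}.
- Degenerate inputs fail loudly: constant silent region in `estimate_snr`,
  rank-deficient designs, singular within-scatter, shifted peak leaving
  the domain.
- Problem sizes in the test suite: full-size datasets (200 × 1024,
  K = 190, 50 components, 10-fold CV) are used for the headline
  region-structure, denoising and chance-level checks; reduced sizes
  (30/class × 256 points, K = 60) for the leakage audit and harness
  mechanics, where the property under test is size-independent.
- Known limitations: only clamped equally spaced knots (no quantile
  placement), no roughness penalties or smoothed FPCA, no Fourier bases,
  no quadratic/shrinkage discriminants, and the simulator's noise model is
  homoscedastic Gaussian.
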