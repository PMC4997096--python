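# Methods

## Model

A binary classifier for short multichannel EEG segments.  A segment
`X ∈ R^{C×T}` (C channels, T samples, assumed zero-mean after filtering) is
summarised by its covariance `Σ = XXᵀ/T` and scored linearly in `Σ`:

```
f(Σ) = b + ⟨Θ, Σ⟩,    P(y=+1 | Σ) = 1 / (1 + e^{−f}),
```

with the coefficient matrix constrained to `rank(Θ) ≤ c`.  The training
problem is the sum of logistic losses over labelled segments subject to the
rank constraint.  The motivation is the classic power-feature model
`f = b + Σ_j θ_j log Var(w_jᵀX)`: dropping the logarithm turns the sum of
weighted filter powers into a trace inner product with
`Θ = Σ_j θ_j w_j w_jᵀ`, so a rank budget of `c` corresponds to learning at
most `c` spatial-filter pairs jointly with the classifier instead of fixing
them beforehand with CSP.

Multi-band analysis band-passes the segment with K filters and stacks the K
per-band covariances into a block-diagonal `(CK)×(CK)` feature.  Since the
trace inner product of block-diagonal matrices decomposes over blocks, one
model weights spatial structure per band (verified as a structural identity
in the tests).

## ADMM solver

The rank constraint set is nonconvex; the fit uses ADMM on the splitting
`min F(Θ,b) + G(Ξ)  s.t.  Θ = Ξ`, where `G` is the indicator of the rank
ball:

1. `(Θ, b)`-update: minimise the smooth logistic-plus-quadratic-penalty
   subproblem by L-BFGS, warm-started from the previous iterate, to a
   gradient tolerance tightened in proportion to the current residuals
   (floor `inner_tol = 1e-10`).
2. `Ξ`-update: `Π_c(Θ + Υ)` by truncated SVD — the Frobenius-optimal
   rank-c approximation.  With `nuclear_weight λ > 0` the singular values
   are first soft-thresholded by `λ/ρ`, which corresponds to adding the sum
   of retained singular values to the objective.
3. scaled dual update `Υ ← Υ + Θ − Ξ`.

Stopping uses the standard scaled criterion: both `‖R‖_F = ‖Θ−Ξ‖_F` and
`‖S‖_F = ρ‖Ξ⁺−Ξ‖_F` below `sqrt(d)·tol_abs + tol_rel·scale`
(`tol_abs = 1e-6`, `tol_rel = 1e-4`, max 500 iterations by default).
Initialisation is deterministic at zero, so a fit is bit-reproducible.
Non-convergence returns a flagged model with full residual histories, never
an exception.  The *feasible* iterate `Ξ` is returned as `Θ`, so the output
rank never exceeds the constraint; the achieved rank is reported.

### Conditioning and the stabilised configuration

Two properties of raw covariance features make the literal iteration slow
or non-convergent in practice:

* **Separability.**  With n segments and `C(C+1)/2 + 1` effective
  parameters, moderately sized EEG feature sets are often linearly
  separable, the logistic minimiser lies at infinity, and the iterates
  drift logarithmically — residuals level off rather than vanish.
* **Geometry.**  The shared (class-independent) covariance structure
  dominates the feature second moment; the loss landscape has long flat
  valleys along rotations of the filter directions, and the projection
  direction can oscillate at low rank.

Two optional, exactly model-preserving remedies are provided and used
throughout the examples and experiment scripts:

* `whiten=True`: features are mapped to `WΣWᵀ` with `W = Σ̄^{-1/2}` (inverse
  square root of the mean training covariance), the fit runs in whitened
  coordinates, and the result is mapped back as `Θ = WᵀΘ'W`.  Because `W`
  is invertible this is a pure preconditioner: the model class and the rank
  constraint are unchanged.  This is the same normalisation step CSP
  performs implicitly.
* `nuclear_weight=1.0`: the soft-threshold in the `Ξ`-update zeroes
  near-flat noise components, removing the directions that converge
  slowest, and regularises coefficient growth on separable data.

Both default to OFF so that the default objective is the pure logistic
loss with a pure projection step.  With `whiten=True, nuclear_weight=1.0,
rho=2.0` the solver reaches residual norms below 1e-5 within a few hundred
iterations on non-separable data at every tested rank; this is the
configuration the acceptance script and the convergence tests run.

Other numerical choices: `ρ = 2.0` in the stabilised configuration
(`1.0` default, fixed; an optional residual-balancing adaptive scheme
exists but is off — it destabilises the nonconvex iteration when it lowers
ρ), spectral ties in the projection resolved by the LAPACK SVD order,
filter signs canonicalised by making each vector's largest-magnitude entry
positive.

## CSP baseline

Standard two-class CSP: class covariances are arithmetic means of segment
covariances; filters solve the generalized eigenproblem `Σ₊w = λΣ₋w`
(solved directly on the pair, not via explicit inversion) normalised to
`wᵀΣ₋w = 1`; the `n_filters/2` eigenvectors from each end of the spectrum
are kept (default 6 filters, 3 + 3).  A tiny diagonal shrinkage
(`1e-10 · trace/C`) guards near-singular covariances.  Features are
`log(wᵀΣw)` with a floor (`1e-12`) against numerically non-positive
projected power.  Baseline classifiers on these features — elastic-net
logistic regression, LDA, QDA, linear SVM, RBF SVM — come from
scikit-learn with library-default hyperparameters (configurable).

## Evaluation protocol

Folds are whole recording sessions: sliding windows (5 s length, 3 s step,
i.e. 2 s overlap; trailing partial windows dropped) are temporally
correlated within a trial, so window-level random splits would leak.  Each
fold holds out one session; CSP filters, classifiers and the low-rank model
are fitted on the remaining sessions only (audited by a leakage test).
Error = misclassified test segments / total test segments.  Folds whose
training part lacks a class are excluded and reported.  The rank sweep
reruns CV per rank constraint and records ADMM iteration counts as a
hardware-independent proxy for convergence time; the band sweep reruns CV
per named band preset (theta 4–7, alpha 8–13, beta 14–29, gamma 30–47,
wide 4–47 Hz) at fixed rank 6.

## Synthetic data generator

The generator emulates the acquisition geometry the model targets —
26 channels at 128 Hz, 80 s trials, 5 sessions with one trial per class —
with a linear forward model `X = A S + E`:

* `A`: fixed unit-norm spatial patterns (default: three smooth,
  exactly orthogonal cosine profiles over the channel index; left/right
  frontal Gaussian-bump templates are available as optional presets).
* `S`: per-pattern sources, each a sum over bands of zero-phase band-passed
  white Gaussian noise rescaled to an exact target variance set by
  `(class, band)` (scalar, or per-pattern vector).  Only second-order
  statistics matter to the classifiers, so Gaussian band-limited sources
  are sufficient.
* `E`: Gaussian noise with channel covariance
  `cov[i,j] = σ² exp(−|i−j|/L)` (default σ² = 1, L = 3; identity available
  for analytically exact tests).

The default class contrast gives the positive class 3× beta and 2.5× gamma
source variance with class-independent theta/alpha power.  No public
reference data exists for this setting, so these magnitudes are
calibration-free choices; the defaults are deliberately strong (near-zero
CV error) so that null-data controls (exact chance) and graded-difficulty
variants bracket the behaviour.  Because each source is rescaled to exact
unit sample variance, the class-conditional population covariance
`Σ_c = Σ_m (Σ_β q_c(β)[m]) a_m a_mᵀ + Σ_noise` is available in closed form
and is checked against empirical estimates.

What the generator does *not* emulate: eye/muscle artifacts, within-trial
nonstationarity, re-referencing or downsampling of a higher-rate
acquisition, volume-conduction forward physics, or inter-subject
variability.  Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted second-order structure, not
performance on real EEG.

## Experiment design choices

* **Convergence contract** runs on 10 channels × 200 segments with a weak
  beta contrast (1.5×) under strong correlated noise (σ² = 4): with
  n = 200 segments against 101 effective parameters generic data would be
  separable and the minimiser infinite, so class overlap is required for a
  meaningful convergence test (13–25 % training error at ranks 1–4).
* **Planted rank-2 recovery** uses two orthogonal patterns with
  complementary contrasts (one 4× at 20–30 Hz for the positive class, the
  other 4× at 8–13 Hz for the negative class) and identity noise, so the
  population discriminant's column space is exactly the pattern span; the
  fitted top-2 left singular subspace is compared by principal angle.
* **Plateau sweep** uses the same structure under σ² = 6 noise: with
  quieter backgrounds a 5 s window's power estimate is precise enough that
  even a rank-1 model separates the classes and the error curve is flat at
  zero.
* Experiments in the test suite and acceptance script run at 8–10 channels
  and 11–62 s trials; the headline CV runs at the full default conditions
  (26 channels, 80 s, 260 segments).  These sizes are the package's own
  choice of compact-but-representative problems.

## Interpretation tools

`decompose_model` truncates the SVD at numerical rank (relative threshold
1e-8), canonicalises signs, reports each singular value's percentage share
and whether `u_i ≈ +v_i` or `−v_i`.  `cluster_filters` pools left singular
vectors across models, aligns signs against a running reference (k-means on
raw sign-ambiguous vectors would split each topography into antipodal
clusters), and runs seeded k-means (default k = 6, Euclidean metric on
unit-norm vectors; both are conventions, not derived quantities).
`filtered_psd` projects segments through one filter and reports per-class
Welch spectra (1 s windows, 50 % overlap).  Scalp-map output is limited to
(channel, x, y, weight) tables against the synthetic grid montage; plotting
is left to downstream tools.

## Known limitations

* The rank-constrained problem is nonconvex: ADMM carries no global
  optimality guarantee, different configurations can reach different local
  solutions, and convergence is monitored (residual histories on every
  model), not proven.
* Only binary classification; no multiclass extension.
* The error-rate definition is misclassified/total.  Note that prose
  definitions of "error rate" in this literature sometimes read as the
  ratio of *correct* classifications; this package always reports error =
  1 − accuracy.
* Baseline hyperparameters are library defaults; no per-method tuning is
  performed, so baseline comparisons are sanity parity checks rather than
  benchmarks.
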