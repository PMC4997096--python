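# lowrankeeg

Fixed low-rank constrained spatial-filter estimation for binary EEG
classification, with the common-spatial-patterns (CSP) baseline it
generalises.

## The problem

Classic power-based EEG decoding (e.g. of affective or motor states) is a
"bottom-up" pipeline: estimate spatial filters `w_j` with CSP, take
log-variance features `log Var(w_j^T X)` of each short segment `X` (C
channels × T samples), then train a classifier on those features.  Filter
estimation is decoupled from the classifier, so the filters are optimal for
a variance-ratio criterion, not for prediction.

This package implements the "top-down" alternative: score a segment by its
covariance matrix `Σ` directly,

```
f(Σ) = b + ⟨Θ, Σ⟩,      rank(Θ) ≤ c,
```

and fit `(Θ, b)` by minimising the logistic loss
`Σ_i log(1 + exp(−y_i f(Σ_i)))` over matrices of rank at most `c`.  Writing
`Θ = Σ_i σ_i u_i v_iᵀ` (SVD), the score is `b + Σ_i σ_i u_iᵀ Σ v_i`: the
rank constraint *is* implicit spatial-filter estimation, with at most `c`
filter pairs learned jointly with the classifier.  On covariance features
`u_i` and `v_i` agree up to sign, so the left singular vectors play the role
of CSP filters.

The nonconvex rank constraint is handled by ADMM with a split variable `Ξ`
and scaled dual `Υ`:

```
Θ^{k+1} = argmin_{Θ,b} F(Θ,b) + (ρ/2)‖Θ − Ξ^k + Υ^k‖²_F
Ξ^{k+1} = Π_c(Θ^{k+1} + Υ^k)        (truncated SVD)
Υ^{k+1} = Υ^k + Θ^{k+1} − Ξ^{k+1}
```

monitored by the primal residual `R = Θ − Ξ` and dual residual
`S = −ρ(Ξ^{k+1} − Ξ^k)`.  The feasible iterate `Ξ` is returned.  Multi-band
analysis stacks per-band covariances into one block-diagonal feature so a
single model selects spatial patterns per frequency band.

Because no public dataset accompanies this problem setting, the package
ships a first-class synthetic EEG generator: band-limited sources with
class-dependent power are mixed through fixed unit-norm spatial patterns
and buried in spatially correlated noise, so every claim is testable against
planted ground truth.

## Worked example

```python
import numpy as np
from lowrankeeg import (FitConfig, admm_fit, default_spec, extract_features,
                        generate_dataset, predict, run_cv)

recs = generate_dataset(default_spec(seed=0))   # 5 sessions x 2 classes, 26 ch
feats = extract_features(recs, band=(4.0, 47.0))  # 260 covariance features
cfg = FitConfig(rank=6, rho=2.0, nuclear_weight=1.0, whiten=True, max_iter=300)

model = admm_fit(feats, [f.label for f in feats], cfg)
proba, pred = predict(model, feats)
print(model.achieved_rank, np.mean(pred != [f.label for f in feats]))

result = run_cv(recs, method="lowrank", rank=6, fit_config=cfg)
print(result.mean_error, result.std_error)
```

prints

```
3 0.0
0.0 0.0
```

i.e. the fitted coefficient matrix uses 3 of its 6 allowed filter pairs
(the nuclear-norm weight zeroes uninformative ones), classifies every
training segment correctly, and session-holdout cross-validation error is
0.0 under the default planted beta/gamma contrast — the same pipeline on
no-contrast data sits at chance (≈0.5, see `examples/` and the test suite).

The `examples/` directory has one narrative script per capability:
generation, fitting, CV against the five CSP baselines (elastic-net
logistic, LDA, QDA, linear/RBF SVM on identical log-variance features),
rank/band sweeps, and filter interpretation (SVD, k-means filter atlas,
per-class Welch spectra).  A thin CLI wraps the same functions:

```bash
lowrankeeg generate --seed 1 --out data/
lowrankeeg fit --rank 6 --config config.yaml --out fit/
lowrankeeg evaluate cv --method lowrank --rank 6 --out results/
lowrankeeg interpret decompose --model fit/model.json --out filters.csv
```

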