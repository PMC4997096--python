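"""Fixed-rank constrained logistic regression on covariance features.

The model scores a segment by the trace inner product of a coefficient
matrix Theta with the segment's covariance,

    f(Sigma) = b + <Theta, Sigma>,

and is trained by minimising the logistic loss

    F(Theta, b) = sum_i log(1 + exp(-y_i f(Sigma_i)))

subject to rank(Theta) <= c.  Constraining the rank is what turns the fit
into implicit spatial-filter estimation: writing Theta = sum_i s_i u_i v_i^T,
the score becomes b + sum_i s_i u_i^T Sigma v_i, i.e. at most c pairs of
spatial filters applied to the covariance from the left and right.

The nonconvex rank constraint is handled by ADMM with a split variable:

    Theta^{k+1} = argmin_{Theta,b} F(Theta, b)
                  + (rho/2) ||Theta - Xi^k + Upsilon^k||_F^2
    Xi^{k+1}    = P_c(Theta^{k+1} + Upsilon^k)      (truncated SVD)
    Upsilon^{k+1} = Upsilon^k + Theta^{k+1} - Xi^{k+1}

with scaled dual variable Upsilon and penalty rho > 0, monitored through the
primal residual R = Theta - Xi and dual residual S = -rho (Xi^{k+1} - Xi^k).
The feasible iterate Xi (exactly rank <= c) is returned as the model's
coefficient matrix.  The problem is nonconvex, so convergence is monitored,
not guaranteed; with the deterministic zero initialisation the fit is
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

from .preprocess import CovFeature

__all__ = [
    "FitConfig",
    "ADMMState",
    "LowRankModel",
    "logistic_objective",
    "rank_projection",
    "theta_update",
    "admm_fit",
    "predict",
    "decision_function",
    "residual_norms",
    "save_model",
    "load_model",
]


@dataclass
class FitConfig:
    """Tunable knobs of the ADMM fit.

    rank
        The rank budget c (>= 1); the number of implicit spatial-filter pairs.
    rho
        ADMM penalty parameter (> 0); fixed by default.  ``adaptive_rho``
        enables the standard residual-balancing update.
    max_iter, tol_abs, tol_rel
        Outer stopping: both residual norms must fall below
        ``sqrt(n_elements) * tol_abs + tol_rel * scale`` with the usual
        primal/dual scales.
    inner_tol, inner_max_iter
        The smooth (Theta, b)-subproblem is solved by L-BFGS to a gradient
        sup-norm tolerance, tightened as outer residuals shrink but never
        below ``inner_tol``.
    nuclear_weight
        Optional nuclear-norm weight applied in the Xi-update as
        soft-thresholding of singular values before truncation; 0 disables it.
        This matches writing the training objective with an additional sum of
        the retained singular values; besides shrinking the coefficients it
        markedly stabilises the nonconvex iteration by zeroing near-flat
        noise components.
    whiten
        Precondition in channel space: features are transformed to
        W Sigma W^T with W the inverse matrix square root of the mean
        training covariance, the fit runs in whitened coordinates, and the
        coefficient matrix is mapped back as Theta = W^T Theta' W.  The
        transform is invertible, so the model class and the rank constraint
        are exactly preserved; only the optimisation geometry changes
        (residual histories refer to the whitened iteration).  Off by
        default: by contract the fitter does not rescale features unless
        asked.
    """

    rank: int = 6
    rho: float = 1.0
    max_iter: int = 500
    tol_abs: float = 1e-6
    tol_rel: float = 1e-4
    inner_tol: float = 1e-10
    inner_max_iter: int = 500
    nuclear_weight: float = 0.0
    adaptive_rho: bool = False
    whiten: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.tol_abs <= 0 or self.tol_rel < 0:
            raise ValueError("tolerances must be positive (tol_rel may be 0)")


@dataclass
class ADMMState:
    """One snapshot of the ADMM iteration (scaled-dual form)."""

    theta: np.ndarray
    xi: np.ndarray
    upsilon: np.ndarray
    bias: float
    rho: float
    iteration: int
    primal_norm: float = np.nan
    dual_norm: float = np.nan


@dataclass
class LowRankModel:
    """A fitted rank-constrained covariance classifier."""

    theta: np.ndarray
    bias: float
    rank_constraint: int
    converged: bool = True
    n_iter: int = 0
    history: dict = field(default_factory=dict)
    config: FitConfig | None = None

    @property
    def achieved_rank(self) -> int:
        s = np.linalg.svd(self.theta, compute_uv=False)
        if s[0] == 0:
            return 0
        return int(np.sum(s > 1e-8 * s[0]))


def _stack(covs: list[CovFeature] | list[np.ndarray]) -> np.ndarray:
    mats = [c.matrix if isinstance(c, CovFeature) else np.asarray(c) for c in covs]
    d = mats[0].shape[0]
    for m in mats:
        if m.shape != (d, d):
            raise ValueError(f"covariance shapes differ: {m.shape} vs {(d, d)}")
    return np.stack([m.ravel() for m in mats])


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    bad = set(np.unique(y)) - {1.0, -1.0}
    if bad:
        raise ValueError(f"labels must be +1 or -1, got {sorted(bad)}")
    return y


def logistic_objective(
    theta: np.ndarray,
    bias: float,
    covs: list[CovFeature] | list[np.ndarray],
    labels,
) -> tuple[float, np.ndarray, float]:
    """Summed logistic loss and its gradients.

    Returns ``(loss, grad_theta, grad_bias)`` where
    loss = sum_i log(1 + exp(-y_i (b + <Theta, Sigma_i>))).  An empty sample
    gives loss 0 and zero gradients (used by penalty-only subproblem tests).
    """
    theta = np.asarray(theta, dtype=float)
    if len(covs) == 0:
        return 0.0, np.zeros_like(theta), 0.0
    y = _check_labels(labels)
    D = _stack(covs)
    f = D @ theta.ravel() + bias
    margins = y * f
    loss = float(np.logaddexp(0.0, -margins).sum())
    # d/df log(1+e^{-yf}) = -y * sigmoid(-y f)
    coef = -y * _sigmoid(-margins)
    grad_theta = (D.T @ coef).reshape(theta.shape)
    grad_bias = float(coef.sum())
    return loss, grad_theta, grad_bias


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def rank_projection(M: np.ndarray, c: int) -> np.ndarray:
    """Best rank-c approximation in Frobenius norm (truncated SVD).

    For c >= min(M.shape) the matrix is returned unchanged.
    """
    if c < 1:
        raise ValueError(f"rank must be >= 1, got {c}")
    M = np.asarray(M, dtype=float)
    if c >= min(M.shape):
        return M.copy()
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (U[:, :c] * s[:c]) @ Vt[:c]


def _shrink_project(M: np.ndarray, c: int, nuclear_weight: float, rho: float
                    ) -> np.ndarray:
    """Xi-update: optionally soft-threshold singular values by weight/rho,
    then truncate to rank c.  With nuclear_weight == 0 this is the pure
    projection."""
    if nuclear_weight <= 0:
        return rank_projection(M, c)
    U, s, Vt = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    s = np.maximum(s - nuclear_weight / rho, 0.0)
    k = min(c, s.size)
    return (U[:, :k] * s[:k]) @ Vt[:k]


def theta_update(
    state: ADMMState,
    D: np.ndarray,
    y: np.ndarray,
    config: FitConfig,
    gtol: float,
) -> tuple[np.ndarray, float]:
    """Approximately minimise F(Theta, b) + (rho/2)||Theta - Xi + Upsilon||_F^2
    jointly in (Theta, b), warm-started from the current iterate."""
    shape = state.theta.shape
    target = (state.xi - state.upsilon).ravel()
    rho = state.rho
    n = D.shape[0] if D.size else 0

    def fun(x):
        vec, b = x[:-1], x[-1]
        if n:
            f = D @ vec + b
            margins = y * f
            loss = np.logaddexp(0.0, -margins).sum()
            coef = -y * _sigmoid(-margins)
            g_vec = D.T @ coef
            g_b = coef.sum()
        else:
            loss, g_vec, g_b = 0.0, np.zeros_like(vec), 0.0
        diff = vec - target
        loss = loss + 0.5 * rho * diff @ diff
        g_vec = g_vec + rho * diff
        grad = np.concatenate([g_vec, [g_b]])
        return loss, grad

    x0 = np.concatenate([state.theta.ravel(), [state.bias]])
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "gtol": gtol,
            "ftol": 1e-16,
            "maxiter": config.inner_max_iter,
            "maxcor": 20,
        },
    )
    if not np.all(np.isfinite(res.x)):
        raise FloatingPointError(
            "inner solver produced non-finite iterates; aborting fit"
        )
    return res.x[:-1].reshape(shape), float(res.x[-1])


def residual_norms(state: ADMMState, xi_prev: np.ndarray | None = None
                   ) -> tuple[float, float]:
    """Frobenius norms of the primal residual R = Theta - Xi and the dual
    residual S = -rho (Xi - Xi_prev).  With no previous Xi the stored dual
    norm is reported."""
    primal = float(np.linalg.norm(state.theta - state.xi))
    if xi_prev is None:
        dual = float(state.dual_norm)
    else:
        dual = float(state.rho * np.linalg.norm(state.xi - xi_prev))
    return primal, dual


def admm_fit(
    covs: list[CovFeature] | list[np.ndarray],
    labels,
    config: FitConfig | None = None,
) -> LowRankModel:
    """Fit the rank-constrained model by ADMM from zero initialisation.

    Stops when both scaled residual criteria hold or ``max_iter`` is reached;
    non-convergence yields ``converged=False`` and a warning, never an
    exception.  The returned coefficient matrix is the feasible split
    variable Xi, so its rank never exceeds the constraint.
    """
    config = config or FitConfig()
    y = _check_labels(labels)
    if len(covs) == 0:
        raise ValueError("no training covariances supplied")
    classes = set(np.unique(y))
    if classes != {1.0, -1.0}:
        raise ValueError(
            f"both classes must be present in training labels, got {classes}"
        )
    D = _stack(covs)
    d = int(np.sqrt(D.shape[1]))
    shape = (d, d)
    W = None
    if config.whiten:
        mean = D.mean(axis=0).reshape(shape)
        evals, evecs = np.linalg.eigh(0.5 * (mean + mean.T))
        floor = max(evals.max(), 0.0) * 1e-12
        if evals.max() <= 0:
            raise ValueError("mean training covariance is not positive; "
                             "cannot whiten")
        evals = np.maximum(evals, floor)
        W = evecs @ np.diag(evals**-0.5) @ evecs.T
        mats = (
            W[None] @ D.reshape(-1, d, d) @ W.T[None]
        )
        D = mats.reshape(len(covs), d * d)
    sqrt_nelem = float(np.sqrt(D.shape[1]))

    state = ADMMState(
        theta=np.zeros(shape),
        xi=np.zeros(shape),
        upsilon=np.zeros(shape),
        bias=0.0,
        rho=config.rho,
        iteration=0,
    )
    history: dict[str, list] = {"loss": [], "primal": [], "dual": [], "rho": []}
    converged = False
    gtol = 1e-6
    for k in range(config.max_iter):
        state.theta, state.bias = theta_update(state, D, y, config, gtol)
        xi_prev = state.xi
        state.xi = _shrink_project(
            state.theta + state.upsilon, config.rank, config.nuclear_weight,
            state.rho,
        )
        state.upsilon = state.upsilon + state.theta - state.xi
        state.iteration = k + 1
        primal, dual = residual_norms(state, xi_prev)
        state.primal_norm, state.dual_norm = primal, dual

        margins = y * (D @ state.xi.ravel() + state.bias)
        loss = float(np.logaddexp(0.0, -margins).sum())
        history["loss"].append(loss)
        history["primal"].append(primal)
        history["dual"].append(dual)
        history["rho"].append(state.rho)

        eps_pri = sqrt_nelem * config.tol_abs + config.tol_rel * max(
            np.linalg.norm(state.theta), np.linalg.norm(state.xi)
        )
        eps_dual = sqrt_nelem * config.tol_abs + config.tol_rel * (
            state.rho * np.linalg.norm(state.upsilon)
        )
        if primal <= eps_pri and dual <= eps_dual:
            converged = True
            break

        # tighten the inner solve as the outer residuals shrink
        gtol = float(np.clip(1e-2 * min(primal, dual), config.inner_tol, 1e-6))

        if config.adaptive_rho and (k + 1) % 10 == 0:
            if primal > 10 * dual:
                state.rho *= 2.0
                state.upsilon /= 2.0
            elif dual > 10 * primal:
                state.rho /= 2.0
                state.upsilon *= 2.0

    if not converged:
        warnings.warn(
            f"ADMM did not reach the residual tolerances in {config.max_iter} "
            f"iterations (primal={state.primal_norm:.2e}, "
            f"dual={state.dual_norm:.2e})",
            stacklevel=2,
        )
    theta_out = state.xi if W is None else W.T @ state.xi @ W
    return LowRankModel(
        theta=theta_out,
        bias=state.bias,
        rank_constraint=config.rank,
        converged=converged,
        n_iter=state.iteration,
        history=history,
        config=config,
    )


def decision_function(
    model: LowRankModel, covs: CovFeature | np.ndarray | list
) -> np.ndarray:
    """Linear scores f = b + <Theta, Sigma> for one or many covariances."""
    single = isinstance(covs, (CovFeature, np.ndarray))
    items = [covs] if single else list(covs)
    D = _stack(items)
    if D.shape[1] != model.theta.size:
        d = int(np.sqrt(D.shape[1]))
        raise ValueError(
            f"covariance shape ({d}, {d}) does not match model coefficient "
            f"shape {model.theta.shape}"
        )
    return D @ model.theta.ravel() + model.bias


def predict(
    model: LowRankModel, covs: CovFeature | np.ndarray | list
) -> tuple[np.ndarray, np.ndarray]:
    """Class probability P(y=+1) and hard label for covariance feature(s).

    The label is +1 when the probability is >= 0.5 (ties to +1).
    """
    f = decision_function(model, covs)
    proba = _sigmoid(f)
    label = np.where(proba >= 0.5, 1, -1)
    if np.ndim(f) and f.shape == (1,) and isinstance(covs, (CovFeature, np.ndarray)):
        return float(proba[0]), int(label[0])
    return proba, label


def save_model(path: str, model: LowRankModel) -> None:
    """Serialise a model to JSON; float round-trip is exact."""
    payload = {
        "theta": model.theta.tolist(),
        "bias": model.bias,
        "rank_constraint": model.rank_constraint,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "history": model.history,
        "config": asdict(model.config) if model.config else None,
    }
    with open(path, "w") as f:
        json.dump(payload, f)


def load_model(path: str) -> LowRankModel:
    with open(path) as f:
        payload = json.load(f)
    config = FitConfig(**payload["config"]) if payload["config"] else None
    return LowRankModel(
        theta=np.array(payload["theta"], dtype=float),
        bias=float(payload["bias"]),
        rank_constraint=int(payload["rank_constraint"]),
        converged=bool(payload["converged"]),
        n_iter=int(payload["n_iter"]),
        history=payload["history"],
        config=config,
    )
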