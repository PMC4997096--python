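"""Session-holdout cross-validation, rank/band sweeps and CSP baselines.

Sliding-window segments are strongly correlated in time within a trial, so
folds are built at the *session* level: each fold holds out one whole
session for testing and fits everything — band filters excepted (they are
data-independent), CSP filters, classifiers, the low-rank model — on the
remaining sessions only.  The error rate is the fraction of misclassified
test segments.

Baseline methods share one feature definition: six CSP filters (three per
spectral extreme) fitted on the training fold, log-variance features, then a
standard classifier (elastic-net logistic regression, LDA, QDA, linear SVM
or RBF SVM) from scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from . import csp as csp_mod
from . import lowrank
from .preprocess import BAND_PRESETS, CovFeature, Recording, extract_features

__all__ = [
    "CVPlan",
    "CVResult",
    "METHODS",
    "make_session_folds",
    "run_cv",
    "rank_sweep",
    "band_sweep",
    "csp_baseline_features",
]

METHODS = (
    "lowrank",
    "csp+elasticnet",
    "csp+lda",
    "csp+qda",
    "csp+lsvm",
    "csp+rsvm",
)


@dataclass
class CVPlan:
    """Session-holdout folds: each session is the test set exactly once."""

    folds: list[tuple[tuple, object]]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class CVResult:
    """Per-fold error rates for one method plus their mean and std."""

    method: str
    fold_errors: list[float]
    fold_test_sessions: list
    mean_error: float
    std_error: float
    fold_iterations: list[int] = field(default_factory=list)
    invalid_folds: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "fold": range(len(self.fold_errors)),
                "test_session": self.fold_test_sessions,
                "error": self.fold_errors,
                "iterations": self.fold_iterations
                or [np.nan] * len(self.fold_errors),
            }
        )


def make_session_folds(recordings: list[Recording]) -> CVPlan:
    """One fold per session, ordered by session id, train/test disjoint."""
    sessions = [r.session_id for r in recordings]
    unique = sorted(set(sessions))
    if len(unique) < 2:
        raise ValueError(
            f"need at least 2 distinct sessions for session-holdout CV, "
            f"got {unique}"
        )
    per_recording = {}
    for r in recordings:
        key = (r.session_id, r.label, r.trial_index)
        if key in per_recording:
            raise ValueError(
                f"duplicate recording identity {key}; session/trial ids must "
                f"be unique"
            )
        per_recording[key] = True
    folds = []
    for test in unique:
        train = tuple(s for s in unique if s != test)
        folds.append((train, test))
    return CVPlan(folds=folds)


def _baseline_classifier(name: str, config: dict):
    params = dict(config.get("classifier_params", {}))
    if name == "elasticnet":
        return LogisticRegression(
            solver="saga",
            l1_ratio=params.pop("l1_ratio", 0.5),
            max_iter=params.pop("max_iter", 5000),
            **params,
        )
    if name == "lda":
        return LinearDiscriminantAnalysis(**params)
    if name == "qda":
        return QuadraticDiscriminantAnalysis(**params)
    if name == "lsvm":
        return SVC(kernel="linear", **params)
    if name == "rsvm":
        return SVC(kernel="rbf", **params)
    raise ValueError(f"unknown baseline classifier {name!r}")


def csp_baseline_features(
    train_covs: list[CovFeature],
    test_covs: list[CovFeature],
    n_filters: int = 6,
) -> tuple[np.ndarray, np.ndarray, csp_mod.FilterBank]:
    """CSP log-variance feature tables with filters fitted on train only."""
    cc = csp_mod.class_covariances(train_covs)
    bank = csp_mod.csp_filters(cc, n_filters=n_filters)
    Xtr = np.array([csp_mod.logvar_features(c, bank) for c in train_covs])
    Xte = np.array([csp_mod.logvar_features(c, bank) for c in test_covs])
    return Xtr, Xte, bank


def _fit_predict_fold(
    method: str,
    train_covs: list[CovFeature],
    test_covs: list[CovFeature],
    config: dict,
) -> tuple[np.ndarray, int]:
    """Fit on the training fold, predict test labels.  Returns predicted
    labels and an iteration count (ADMM iterations; 0 for baselines)."""
    if method == "lowrank":
        fit_config = config.get("fit_config") or lowrank.FitConfig(
            rank=config.get("rank", 6)
        )
        y_train = [c.label for c in train_covs]
        model = lowrank.admm_fit(train_covs, y_train, fit_config)
        _, labels = lowrank.predict(model, test_covs)
        return np.asarray(labels), model.n_iter
    if method.startswith("csp+"):
        name = method.split("+", 1)[1]
        Xtr, Xte, _ = csp_baseline_features(
            train_covs, test_covs, n_filters=config.get("n_filters", 6)
        )
        clf = _baseline_classifier(name, dict(config))
        clf.fit(Xtr, [c.label for c in train_covs])
        return np.asarray(clf.predict(Xte)), 0
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_cv(
    recordings: list[Recording],
    method: str = "lowrank",
    band: tuple[float, float] | None = BAND_PRESETS["wide"],
    bands: list[tuple[float, float]] | None = None,
    window_len: float = 5.0,
    step: float = 3.0,
    normalize: str = "samples",
    **config,
) -> CVResult:
    """Session-holdout CV of one method.

    A fold whose training part lacks one class is marked invalid, excluded
    from the aggregate, and reported in ``invalid_folds``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    plan = make_session_folds(recordings)
    features = extract_features(
        recordings,
        band=band,
        bands=bands,
        window_len=window_len,
        step=step,
        normalize=normalize,
    )
    fold_errors, fold_sessions, fold_iters, invalid = [], [], [], []
    for train_sessions, test_session in plan.folds:
        train = [c for c in features if c.session_id in train_sessions]
        test = [c for c in features if c.session_id == test_session]
        train_labels = {c.label for c in train}
        if train_labels != {+1, -1} or not test:
            invalid.append(test_session)
            continue
        pred, n_iter = _fit_predict_fold(method, train, test, config)
        truth = np.array([c.label for c in test])
        fold_errors.append(float(np.mean(pred != truth)))
        fold_sessions.append(test_session)
        fold_iters.append(n_iter)
    if not fold_errors:
        raise ValueError("no valid folds: every fold lacked a class")
    return CVResult(
        method=method,
        fold_errors=fold_errors,
        fold_test_sessions=fold_sessions,
        mean_error=float(np.mean(fold_errors)),
        std_error=float(np.std(fold_errors)),
        fold_iterations=fold_iters,
        invalid_folds=invalid,
        config={
            "band": band,
            "bands": bands,
            "window_len": window_len,
            "step": step,
            "normalize": normalize,
            **{k: v for k, v in config.items() if k != "fit_config"},
        },
    )


def rank_sweep(
    recordings: list[Recording],
    ranks: list[int],
    band: tuple[float, float] | None = BAND_PRESETS["wide"],
    bands: list[tuple[float, float]] | None = None,
    fit_config: lowrank.FitConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """One CV run per rank constraint with shared folds and features.

    ADMM iteration counts stand in for wall-clock convergence time, so the
    comparison across ranks is hardware-independent.
    """
    if not ranks:
        raise ValueError("ranks list is empty")
    rows = []
    for c in ranks:
        cfg = fit_config
        if cfg is not None:
            cfg = lowrank.FitConfig(**{**cfg.__dict__, "rank": c})
        result = run_cv(
            recordings,
            method="lowrank",
            band=band,
            bands=bands,
            rank=c,
            fit_config=cfg,
            **kwargs,
        )
        rows.append(
            {
                "rank": c,
                "mean_error": result.mean_error,
                "std_error": result.std_error,
                "mean_iterations": float(np.mean(result.fold_iterations)),
            }
        )
    return pd.DataFrame(rows)


def band_sweep(
    recordings: list[Recording],
    bands: dict[str, tuple[float, float]] | None = None,
    rank: int = 6,
    fit_config: lowrank.FitConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """One CV run per named band preset at a fixed rank constraint."""
    if bands is None:
        bands = dict(BAND_PRESETS)
    if not bands:
        raise ValueError("band preset list is empty")
    rows = []
    for name, band in bands.items():
        cfg = fit_config
        if cfg is not None:
            cfg = lowrank.FitConfig(**{**cfg.__dict__, "rank": rank})
        result = run_cv(
            recordings,
            method="lowrank",
            band=band,
            rank=rank,
            fit_config=cfg,
            **kwargs,
        )
        rows.append(
            {
                "band": name,
                "low": band[0],
                "high": band[1],
                "mean_error": result.mean_error,
                "std_error": result.std_error,
            }
        )
    return pd.DataFrame(rows)
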