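"""Common spatial patterns: the conventional two-class baseline.

CSP seeks channel-weight vectors w extremizing the variance ratio
w^T S+ w / w^T S- w between the two class covariances.  Rescaling w leaves
the ratio unchanged, so the problem is solved as the generalized eigenproblem

    S+ w = lambda S- w,   with w^T S- w = 1,

and the filters at both ends of the spectrum (largest and smallest lambda)
are kept.  Segments are then summarised by log-variance features
log(w_j^T Sigma w_j), the classic input to a linear classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .preprocess import CovFeature, Segment, segment_covariance

__all__ = [
    "ClassCovariances",
    "FilterBank",
    "class_covariances",
    "csp_filters",
    "logvar_features",
]


@dataclass
class ClassCovariances:
    """Mean covariance per class plus the segment counts behind each mean."""

    sigma_pos: np.ndarray
    sigma_neg: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class FilterBank:
    """Spatial filters as columns of ``filters`` (C x J) with eigenvalues.

    ``sides[j]`` records which end of the spectrum filter j came from:
    "high" (largest lambda, maximal positive-class variance) or "low".
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    sides: list[str]

    @property
    def n_filters(self) -> int:
        return self.filters.shape[1]

    def to_frame(self, channel_names: list[str] | None = None):
        import pandas as pd

        C = self.filters.shape[0]
        names = channel_names or [f"CH{i + 1:02d}" for i in range(C)]
        df = pd.DataFrame(
            self.filters,
            index=names,
            columns=[f"w{j + 1}_{s}" for j, s in enumerate(self.sides)],
        )
        return df


def class_covariances(covs: list[CovFeature]) -> ClassCovariances:
    """Arithmetic mean of segment covariances per class.

    Requires both classes to be present; the per-segment covariances carry
    whatever normalisation the preprocessing chose.
    """
    pos = [c.matrix for c in covs if c.label == +1]
    neg = [c.matrix for c in covs if c.label == -1]
    for name, group in (("+1", pos), ("-1", neg)):
        if not group:
            raise ValueError(f"no segments with class label {name}")
    return ClassCovariances(
        sigma_pos=np.mean(pos, axis=0),
        sigma_neg=np.mean(neg, axis=0),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _canonical_sign(w: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry positive (filters are sign-ambiguous)."""
    i = int(np.argmax(np.abs(w)))
    return -w if w[i] < 0 else w


def csp_filters(
    cc: ClassCovariances, n_filters: int = 6, shrinkage: float = 1e-10
) -> FilterBank:
    """Solve S+ w = lambda S- w and keep both spectral extremes.

    Returns n_filters/2 eigenvectors of largest lambda and n_filters/2 of
    smallest, each normalised to w^T S- w = 1, eigenvalues sorted descending
    within each half.  A small diagonal shrinkage ``shrinkage * trace/C * I``
    guards near-singular class covariances.
    """
    if n_filters % 2 != 0 or n_filters < 2:
        raise ValueError(f"n_filters must be a positive even count, got {n_filters}")
    C = cc.sigma_pos.shape[0]
    if n_filters > C:
        raise ValueError(f"n_filters={n_filters} exceeds channel count {C}")
    sp = 0.5 * (cc.sigma_pos + cc.sigma_pos.T)
    sn = 0.5 * (cc.sigma_neg + cc.sigma_neg.T)
    if shrinkage > 0:
        sp = sp + shrinkage * (np.trace(sp) / C) * np.eye(C)
        sn = sn + shrinkage * (np.trace(sn) / C) * np.eye(C)
    try:
        # scipy normalises generalized eigenvectors to w^T S- w = 1 already
        eigvals, eigvecs = linalg.eigh(sp, sn)
    except linalg.LinAlgError as e:
        raise ValueError(
            "negative-class covariance is singular; increase the shrinkage "
            "parameter or supply better-conditioned covariances"
        ) from e
    order = np.argsort(eigvals)[::-1]  # descending
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    half = n_filters // 2
    idx = list(range(half)) + list(range(C - half, C))
    sides = ["high"] * half + ["low"] * half
    W = np.column_stack([_canonical_sign(eigvecs[:, i]) for i in idx])
    return FilterBank(filters=W, eigenvalues=eigvals[idx], sides=sides)


def logvar_features(
    item: Segment | CovFeature, bank: FilterBank, floor: float = 1e-12
) -> np.ndarray:
    """Log-variance feature vector: element j is log(w_j^T Sigma w_j).

    Sigma is the segment covariance (computed on the fly for a Segment).
    Non-positive projected power — possible only through numerical
    degeneracy — is clamped at ``floor`` with a warning rather than letting
    -inf propagate.
    """
    if isinstance(item, Segment):
        sigma = segment_covariance(item).matrix
    else:
        sigma = item.matrix
    W = bank.filters
    if W.shape[0] != sigma.shape[0]:
        raise ValueError(
            f"filter length {W.shape[0]} does not match covariance size "
            f"{sigma.shape[0]}"
        )
    power = np.einsum("cj,cd,dj->j", W, sigma, W)
    if np.any(power <= floor):
        warnings.warn(
            "projected variance at or below floor; clamping before log",
            stacklevel=2,
        )
        power = np.maximum(power, floor)
    return np.log(power)
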