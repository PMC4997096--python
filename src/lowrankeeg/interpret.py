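"""Turn fitted rank-constrained models into interpretable spatial filters.

Writing the coefficient matrix as Theta = sum_i s_i u_i v_i^T (SVD), the
linear score b + <Theta, Sigma> becomes b + sum_i s_i u_i^T Sigma v_i: each
singular pair (u_i, v_i) acts as a pair of spatial filters applied to the
segment covariance from the left and right, weighted by s_i.  Because the
model effectively measures power, u_i and v_i typically agree up to sign;
the left singular vectors are taken as *the* spatial filters.

Filters pooled across many fitted models (sign-ambiguous by nature) can be
sign-aligned and clustered with k-means to find recurring topographies, and
a filter's effect on the signal is characterised by comparing per-class
Welch power spectral densities of the spatially filtered segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.cluster import KMeans

from .lowrank import LowRankModel
from .preprocess import Segment

__all__ = [
    "ModelDecomposition",
    "FilterAtlas",
    "decompose_model",
    "cluster_filters",
    "filtered_psd",
]


@dataclass
class ModelDecomposition:
    """SVD of a fitted model restricted to its numerical rank.

    ``percentiles`` gives each singular value's share of their sum, in
    percent; ``sign_agree[i]`` is True when u_i ~ +v_i (the power-like case)
    and False when u_i ~ -v_i.
    """

    singular_values: np.ndarray
    left: np.ndarray
    right: np.ndarray
    sign_agree: np.ndarray
    percentiles: np.ndarray
    note: str = ""

    @property
    def rank(self) -> int:
        return self.singular_values.size

    def to_frame(self, channel_names: list[str] | None = None) -> pd.DataFrame:
        C = self.left.shape[0]
        names = channel_names or [f"CH{i + 1:02d}" for i in range(C)]
        df = pd.DataFrame(
            self.left, index=names,
            columns=[f"u{i + 1}" for i in range(self.rank)],
        )
        return df


@dataclass
class FilterAtlas:
    """Filters pooled over models with k-means cluster structure.

    ``provenance`` has one row per pooled filter (model id, component index,
    singular-value percentile); ``assignments`` maps each filter to its
    cluster; ``centroids`` are unit-norm representative filters.
    """

    filters: np.ndarray
    provenance: pd.DataFrame
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float

    @property
    def k(self) -> int:
        return self.centroids.shape[1]

    def centroid_frame(self, channel_names: list[str] | None = None) -> pd.DataFrame:
        C = self.centroids.shape[0]
        names = channel_names or [f"CH{i + 1:02d}" for i in range(C)]
        return pd.DataFrame(
            self.centroids, index=names,
            columns=[f"centroid{i + 1}" for i in range(self.k)],
        )


def decompose_model(model: LowRankModel, rel_tol: float = 1e-8
                    ) -> ModelDecomposition:
    """SVD of the model coefficient matrix, truncated to numerical rank.

    Signs are canonicalised: each u_i has its largest-magnitude entry
    positive, and v_i's sign is set so that s_i u_i v_i^T reconstructs Theta.
    A zero coefficient matrix yields an empty decomposition with a note.
    """
    U, s, Vt = np.linalg.svd(model.theta)
    if s.size == 0 or s[0] <= 0:
        C = model.theta.shape[0]
        return ModelDecomposition(
            singular_values=np.empty(0),
            left=np.empty((C, 0)),
            right=np.empty((C, 0)),
            sign_agree=np.empty(0, dtype=bool),
            percentiles=np.empty(0),
            note="zero coefficient matrix: no spatial filters to extract",
        )
    r = int(np.sum(s > rel_tol * s[0]))
    U, s, V = U[:, :r], s[:r], Vt[:r].T
    for i in range(r):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    agree = np.array([float(U[:, i] @ V[:, i]) >= 0 for i in range(r)])
    return ModelDecomposition(
        singular_values=s,
        left=U,
        right=V,
        sign_agree=agree,
        percentiles=100.0 * s / s.sum(),
    )


def _sign_align(filters: np.ndarray) -> np.ndarray:
    """Resolve sign ambiguity: flip each filter to correlate positively with
    a running reference (the mean of already-aligned filters)."""
    aligned = filters.copy()
    ref = aligned[:, 0].copy()
    for i in range(1, aligned.shape[1]):
        if aligned[:, i] @ ref < 0:
            aligned[:, i] = -aligned[:, i]
        ref = ref + aligned[:, i]
    return aligned


def cluster_filters(
    decompositions: list[ModelDecomposition], k: int = 6, seed: int = 0
) -> FilterAtlas:
    """Pool left singular vectors across models and k-means cluster them.

    Filters are sign-aligned first (k-means on raw sign-ambiguous vectors
    would split each topography into two antipodal clusters); centroids are
    renormalised to unit length.  k defaults to 6, one representative per
    rank-6 filter slot.
    """
    cols, rows = [], []
    for m, dec in enumerate(decompositions):
        for i in range(dec.rank):
            cols.append(dec.left[:, i])
            rows.append(
                {
                    "model": m,
                    "component": i,
                    "percentile": float(dec.percentiles[i]),
                    "sign_agree": bool(dec.sign_agree[i]),
                }
            )
    if len(cols) < k:
        raise ValueError(
            f"k={k} exceeds the pooled filter count {len(cols)}"
        )
    pooled = _sign_align(np.column_stack(cols))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assignments = km.fit_predict(pooled.T)
    centroids = km.cluster_centers_.T
    norms = np.linalg.norm(centroids, axis=0)
    norms[norms == 0] = 1.0
    centroids = centroids / norms
    return FilterAtlas(
        filters=pooled,
        provenance=pd.DataFrame(rows),
        assignments=assignments,
        centroids=centroids,
        inertia=float(km.inertia_),
    )


def filtered_psd(
    segments: list[Segment],
    filt: np.ndarray,
    seg_len: float = 1.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Per-class mean Welch PSD of spatially filtered segments.

    Each segment is projected to a single channel w^T X; its PSD is the
    Welch averaged periodogram (``seg_len``-second windows, fractional
    ``overlap``); the mean and standard deviation over segments are reported
    per class and frequency bin up to Nyquist.

    Returns a tidy frame with columns (frequency, label, mean, std, n).
    """
    filt = np.asarray(filt, dtype=float)
    if np.linalg.norm(filt) == 0:
        raise ValueError("spatial filter is identically zero")
    if not segments:
        raise ValueError("no segments supplied")
    if filt.shape[0] != segments[0].n_channels:
        raise ValueError(
            f"filter length {filt.shape[0]} does not match channel count "
            f"{segments[0].n_channels}"
        )
    by_label: dict[int, list[np.ndarray]] = {}
    freqs = None
    for seg in segments:
        x = filt @ seg.data
        nperseg = min(int(round(seg_len * seg.fs)), x.size)
        f, p = signal.welch(
            x, fs=seg.fs, nperseg=nperseg,
            noverlap=int(round(overlap * nperseg)),
        )
        freqs = f
        by_label.setdefault(seg.label, []).append(p)
    frames = []
    for label, psds in sorted(by_label.items(), reverse=True):
        arr = np.stack(psds)
        frames.append(
            pd.DataFrame(
                {
                    "frequency": freqs,
                    "label": label,
                    "mean": arr.mean(axis=0),
                    "std": arr.std(axis=0),
                    "n": arr.shape[0],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
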