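"""Synthetic multi-session EEG with planted class-dependent band power.

The generative model is a linear forward (mixing) model: a small number of
fixed unit-norm spatial patterns ``a_m`` (columns of A) each carry an
oscillatory source, and the scalp signal is

    X = A S + E,

where row m of S is a sum over frequency bands of band-limited Gaussian
noise whose variance depends on the trial's class, and E is spatially
correlated Gaussian background noise with a configurable channel covariance.
Class information therefore lives purely in second-order statistics — the
per-band power routed through each pattern — which is exactly what
covariance-based classifiers (CSP, rank-constrained linear models on
covariances) are built to pick up.

Each band-limited source is rescaled to have *exactly* the target sample
variance, so the class-conditional population covariance is available in
closed form (:func:`analytic_class_covariance`) up to cross-terms between
independent sources.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Recording, bandpass_array

__all__ = [
    "GeneratorSpec",
    "default_spec",
    "generate_dataset",
    "analytic_class_covariance",
    "exponential_noise_cov",
    "smooth_patterns",
    "hemispheric_patterns",
    "grid_montage",
    "save_dataset",
    "load_dataset",
]

CLASS_LABELS = (+1, -1)


def exponential_noise_cov(
    n_channels: int, variance: float = 1.0, corr_length: float = 3.0
) -> np.ndarray:
    """Background-noise covariance with exponentially decaying spatial
    correlation by channel index: ``cov[i, j] = variance * exp(-|i-j|/L)``.

    Neighbouring EEG electrodes see correlated noise (volume conduction);
    ``corr_length=0`` degenerates to white (identity-scaled) noise.
    """
    idx = np.arange(n_channels)
    if corr_length <= 0:
        return variance * np.eye(n_channels)
    return variance * np.exp(-np.abs(idx[:, None] - idx[None, :]) / corr_length)


def grid_montage(n_channels: int) -> pd.DataFrame:
    """A simple synthetic 2-D electrode layout: rows front-to-back on a
    [-1, 1]^2 square, generic channel names CH01, CH02, ...

    Good enough to export (channel, x, y, weight) tables for downstream
    topography tools; it makes no claim to match a real cap.
    """
    n_cols = int(np.ceil(np.sqrt(n_channels)))
    n_rows = int(np.ceil(n_channels / n_cols))
    names, xs, ys = [], [], []
    k = 0
    for r in range(n_rows):
        y = 1.0 - 2.0 * r / max(n_rows - 1, 1)
        in_row = min(n_cols, n_channels - k)
        for c in range(in_row):
            x = -1.0 + 2.0 * c / max(in_row - 1, 1) if in_row > 1 else 0.0
            names.append(f"CH{k + 1:02d}")
            xs.append(x)
            ys.append(y)
            k += 1
    return pd.DataFrame({"channel": names, "x": xs, "y": ys})


def smooth_patterns(n_channels: int, n_patterns: int) -> np.ndarray:
    """Deterministic unit-norm spatial patterns: low-order cosine profiles
    over the channel index (smooth across the montage, mutually distinct).

    Returns an array of shape (n_channels, n_patterns).
    """
    idx = np.arange(n_channels)
    cols = []
    for m in range(n_patterns):
        v = np.cos(np.pi * (m + 1) * (idx + 0.5) / n_channels)
        cols.append(v / np.linalg.norm(v))
    return np.column_stack(cols)


def hemispheric_patterns(montage: pd.DataFrame) -> np.ndarray:
    """Left-frontal and right-frontal pattern templates from a 2-D layout.

    Each pattern is a Gaussian bump centred over one frontal hemisphere,
    normalised to unit length — a stylised stand-in for the frontal
    lateralisation discussed in affective EEG work.  Offered as an optional
    preset, not a default.
    """
    xy = montage[["x", "y"]].to_numpy()
    out = []
    for cx in (-0.6, 0.6):
        centre = np.array([cx, 0.8])
        d2 = ((xy - centre) ** 2).sum(axis=1)
        v = np.exp(-d2 / (2 * 0.35**2))
        out.append(v / np.linalg.norm(v))
    return np.column_stack(out)


@dataclass
class GeneratorSpec:
    """Everything needed to generate one labelled multi-session dataset.

    ``patterns`` is (n_channels, n_patterns) with unit-norm columns.
    ``class_band_power`` maps ``(class_label, (low, high))`` to the source
    variance for that band and class — a scalar applied to every pattern, or
    a length-n_patterns vector for per-pattern control.  ``noise_cov`` is the
    channel covariance of the additive background noise.  All randomness
    flows from ``seed`` through a single generator state.
    """

    n_channels: int = 26
    fs: float = 128.0
    trial_len: float = 80.0
    n_sessions: int = 5
    trials_per_session_per_class: int = 1
    patterns: np.ndarray | None = None
    class_band_power: dict[tuple[int, tuple[float, float]], float | np.ndarray] = field(
        default_factory=dict
    )
    noise_cov: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patterns is None:
            self.patterns = smooth_patterns(self.n_channels, 1)
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        if self.patterns.shape[0] != self.n_channels:
            raise ValueError(
                f"patterns have {self.patterns.shape[0]} rows for "
                f"{self.n_channels} channels"
            )
        if self.noise_cov is None:
            self.noise_cov = exponential_noise_cov(self.n_channels)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        self.validate()

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def bands(self) -> list[tuple[float, float]]:
        """Distinct bands named anywhere in class_band_power, ordered."""
        seen: list[tuple[float, float]] = []
        for _, band in self.class_band_power:
            if band not in seen:
                seen.append(band)
        return seen

    def band_power(self, label: int, band: tuple[float, float]) -> np.ndarray:
        """Per-pattern source variance for (label, band); 0 if unset."""
        v = self.class_band_power.get((label, band), 0.0)
        return np.broadcast_to(np.asarray(v, dtype=float), (self.n_patterns,))

    def validate(self) -> None:
        norms = np.linalg.norm(self.patterns, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError(
                f"pattern columns must be unit-norm, got norms {norms}"
            )
        for label, band in self.class_band_power:
            if label not in CLASS_LABELS:
                raise ValueError(f"class labels must be +1/-1, got {label}")
            low, high = band
            if not (0 < low < high < self.fs / 2):
                raise ValueError(f"band {band} invalid for fs={self.fs}")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-12):
            raise ValueError("noise_cov must be symmetric")
        try:
            np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError as e:
            raise ValueError(
                "noise_cov must be positive definite (Cholesky failed); "
                "check its eigenvalues"
            ) from e


def default_spec(seed: int = 0, **overrides) -> GeneratorSpec:
    """The default study conditions: 26 channels at 128 Hz, 80 s trials,
    5 sessions with one trial per class each, three smooth spatial patterns,
    and a positive class with stronger beta (14-29 Hz) and gamma (30-47 Hz)
    source power; theta/alpha power is class-independent.
    """
    n_channels = overrides.pop("n_channels", 26)
    patterns = overrides.pop("patterns", smooth_patterns(n_channels, 3))
    class_band_power = overrides.pop(
        "class_band_power",
        {
            (+1, (4.0, 7.0)): 1.0,
            (-1, (4.0, 7.0)): 1.0,
            (+1, (8.0, 13.0)): 1.0,
            (-1, (8.0, 13.0)): 1.0,
            (+1, (14.0, 29.0)): 3.0,
            (-1, (14.0, 29.0)): 1.0,
            (+1, (30.0, 47.0)): 2.5,
            (-1, (30.0, 47.0)): 1.0,
        },
    )
    noise_cov = overrides.pop(
        "noise_cov", exponential_noise_cov(n_channels, variance=1.0, corr_length=3.0)
    )
    return GeneratorSpec(
        n_channels=n_channels,
        patterns=patterns,
        class_band_power=class_band_power,
        noise_cov=noise_cov,
        seed=seed,
        **overrides,
    )


def _band_source(
    rng: np.random.Generator, n: int, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-variance band-limited Gaussian source of length n."""
    white = rng.standard_normal(n)
    src = bandpass_array(white, band, fs)
    sd = src.std()
    if sd == 0:
        return src
    return src / sd


def generate_dataset(spec: GeneratorSpec) -> list[Recording]:
    """Generate ``n_sessions * 2 * trials_per_session_per_class`` recordings.

    Recordings are produced in a fixed order (session, class +1 then -1,
    trial) from a single seeded generator, so the same spec regenerates
    bit-identical data.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.trial_len * spec.fs))
    L = np.linalg.cholesky(spec.noise_cov)
    bands = spec.bands()
    recordings: list[Recording] = []
    names = [f"CH{i + 1:02d}" for i in range(spec.n_channels)]
    for session in range(spec.n_sessions):
        for label in CLASS_LABELS:
            for trial in range(spec.trials_per_session_per_class):
                S = np.zeros((spec.n_patterns, T))
                for band in bands:
                    power = spec.band_power(label, band)
                    for m in range(spec.n_patterns):
                        if power[m] <= 0:
                            continue
                        S[m] += np.sqrt(power[m]) * _band_source(
                            rng, T, band, spec.fs
                        )
                noise = L @ rng.standard_normal((spec.n_channels, T))
                X = spec.patterns @ S + noise
                recordings.append(
                    Recording(
                        data=X,
                        fs=spec.fs,
                        channel_names=list(names),
                        session_id=session,
                        label=label,
                        trial_index=trial,
                    )
                )
    return recordings


def analytic_class_covariance(
    spec: GeneratorSpec, label: int, band: tuple[float, float] | None = None
) -> np.ndarray:
    """Population channel covariance for one class under the mixing model.

    Sources for different (pattern, band) pairs are independent and each is
    rescaled to exact unit sample variance, so

        Sigma_c = sum_m (sum_beta q_c(beta)[m]) a_m a_m^T + noise_cov.

    With ``band`` given, only source bands fully inside it contribute and the
    broadband noise is attenuated by the ideal-filter power fraction
    ``(high - low) / (fs / 2)`` (exact for white noise; colored spatial
    structure is frequency-flat here).
    """
    A = spec.patterns
    total = np.zeros((spec.n_channels, spec.n_channels))
    for src_band in spec.bands():
        q = spec.band_power(label, src_band)
        if band is not None:
            lo, hi = band
            if not (lo <= src_band[0] and src_band[1] <= hi):
                continue
        total += A @ np.diag(q) @ A.T
    if band is None:
        noise = spec.noise_cov
    else:
        frac = (band[1] - band[0]) / (spec.fs / 2.0)
        noise = frac * spec.noise_cov
    return total + noise


def save_dataset(directory: str, recordings: list[Recording],
                 montage: pd.DataFrame | None = None) -> None:
    """Write one .npy array per recording plus manifest.csv and montage.csv."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    fs = None
    for i, rec in enumerate(recordings):
        fname = f"recording_{i:04d}.npy"
        np.save(os.path.join(directory, fname), rec.data)
        rows.append(
            {
                "file": fname,
                "session": rec.session_id,
                "class": rec.label,
                "trial": rec.trial_index,
            }
        )
        fs = rec.fs
    pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.csv"), index=False)
    if montage is None and recordings:
        montage = grid_montage(recordings[0].n_channels)
    if montage is not None:
        montage.to_csv(os.path.join(directory, "montage.csv"), index=False)
    with open(os.path.join(directory, "meta.json"), "w") as f:
        json.dump({"fs": fs}, f)


def load_dataset(directory: str) -> list[Recording]:
    """Load a dataset written by :func:`save_dataset`."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    with open(os.path.join(directory, "meta.json")) as f:
        fs = json.load(f)["fs"]
    montage_path = os.path.join(directory, "montage.csv")
    names = None
    if os.path.exists(montage_path):
        names = pd.read_csv(montage_path)["channel"].tolist()
    recordings = []
    for _, row in manifest.iterrows():
        data = np.load(os.path.join(directory, row["file"]))
        recordings.append(
            Recording(
                data=data,
                fs=fs,
                channel_names=list(names) if names else [],
                session_id=int(row["session"]),
                label=int(row["class"]),
                trial_index=int(row["trial"]),
            )
        )
    return recordings
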