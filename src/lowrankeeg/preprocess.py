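"""Turn multichannel EEG recordings into labelled covariance features.

The classification pipeline is: band-pass filter whole trials, cut them into
overlapping sliding windows, and summarise each window by its channel-space
covariance matrix.  For multi-band analysis the per-band covariances of one
window are stacked into a block-diagonal matrix, so a single linear model can
weight spatial patterns in every band jointly.

The pipeline order is fixed as filter-then-window: trials are filtered as a
whole and the windows are cut afterwards, so window edges carry no extra
filter transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import linalg, signal

__all__ = [
    "Recording",
    "Segment",
    "BandSpec",
    "CovFeature",
    "BAND_PRESETS",
    "bandpass",
    "sliding_windows",
    "segment_covariance",
    "multiband_covariance",
    "extract_features",
    "save_features",
    "load_features",
]

#: Named frequency bands (Hz) used throughout: theta, alpha, beta, gamma and
#: the wide band covering all of them.
BAND_PRESETS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 29.0),
    "gamma": (30.0, 47.0),
    "wide": (4.0, 47.0),
}


@dataclass
class Recording:
    """One trial of continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        The signal, channels by time.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per row of ``data``.
    session_id : int or str
        Which recording session the trial belongs to; cross-validation folds
        are built from these.
    label : int or None
        Binary class label in ``{+1, -1}``, or ``None`` for unlabelled data.
    trial_index : int
        Index of the trial within its (session, class) cell.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    session_id: int | str = 0
    label: int | None = None
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording.data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"CH{i + 1:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.label is not None and self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass
class Segment:
    """A fixed-length window cut from a Recording; the unit of classification."""

    data: np.ndarray
    fs: float
    label: int | None = None
    session_id: int | str = 0
    start: float = 0.0
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Segment.data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Segment.data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class BandSpec:
    """An ordered list of (low, high) pass bands in Hz."""

    bands: list[tuple[float, float]]

    def validate(self, fs: float) -> None:
        for low, high in self.bands:
            _check_band((low, high), fs)

    def __len__(self) -> int:
        return len(self.bands)


@dataclass
class CovFeature:
    """A symmetric PSD covariance feature for one segment.

    ``matrix`` is C x C for a single band, or block-diagonal (C*K) x (C*K)
    for K bands with all off-diagonal blocks exactly zero.
    """

    matrix: np.ndarray
    n_bands: int = 1
    label: int | None = None
    session_id: int | str = 0
    start: float = 0.0
    trial_index: int = 0
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("CovFeature.matrix must be square")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def _check_band(band: tuple[float, float], fs: float) -> None:
    low, high = band
    if not (0.0 < low < high):
        raise ValueError(f"band edges must satisfy 0 < low < high, got {band}")
    if high >= fs / 2:
        raise ValueError(
            f"band edge {high} Hz is at or above the Nyquist frequency "
            f"{fs / 2} Hz for fs={fs}"
        )


def design_bandpass(
    band: tuple[float, float], fs: float, order: int = 4
) -> np.ndarray:
    """Design a Butterworth band-pass filter, returned in SOS form."""
    _check_band(band, fs)
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def bandpass(
    recording: Recording, band: tuple[float, float], order: int = 4
) -> Recording:
    """Zero-phase band-pass filter a recording.

    Applies a Butterworth filter forward and backward (``sosfiltfilt``), so
    the output has no group delay; the input is untouched.
    """
    sos = design_bandpass(band, recording.fs, order=order)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return replace(recording, data=filtered)


def bandpass_array(
    data: np.ndarray, band: tuple[float, float], fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase band-pass an array along its last axis."""
    sos = design_bandpass(band, fs, order=order)
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def sliding_windows(
    recording: Recording, window_len: float = 5.0, step: float = 3.0
) -> list[Segment]:
    """Cut a recording into fully contained sliding windows.

    Windows start at 0, step, 2*step, ... seconds; any final partial window
    is dropped.  With the defaults (5 s windows, 3 s step, i.e. 2 s overlap)
    an 80 s trial yields ``floor((80 - 5)/3) + 1 = 26`` segments.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if window_len <= 0:
        raise ValueError(f"window_len must be positive, got {window_len}")
    n_win = int(round(window_len * recording.fs))
    n_step = int(round(step * recording.fs))
    total = recording.data.shape[1]
    if n_win > total:
        warnings.warn(
            f"window of {window_len} s ({n_win} samples) longer than recording "
            f"({total} samples); returning no segments",
            stacklevel=2,
        )
        return []
    segments = []
    for i, start in enumerate(range(0, total - n_win + 1, n_step)):
        segments.append(
            Segment(
                data=recording.data[:, start : start + n_win],
                fs=recording.fs,
                label=recording.label,
                session_id=recording.session_id,
                start=start / recording.fs,
                trial_index=recording.trial_index,
            )
        )
    return segments


def segment_covariance(
    segment: Segment, center: bool = True, normalize: str = "samples"
) -> CovFeature:
    """Channel-space covariance of one segment.

    normalize:
      * ``"samples"`` — X X^T / T (default; commensurable across window sizes)
      * ``"none"``    — raw X X^T
      * ``"trace"``   — X X^T scaled to unit trace

    The EEG is assumed (approximately) zero-mean after high-pass filtering;
    ``center=True`` removes the per-channel mean explicitly.
    """
    X = segment.data
    if X.shape[1] < 2:
        raise ValueError("segment must have at least 2 samples")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    M = X @ X.T
    M = 0.5 * (M + M.T)  # exact symmetry
    if normalize == "samples":
        M = M / X.shape[1]
    elif normalize == "trace":
        tr = np.trace(M)
        if tr > 0:
            M = M / tr
    elif normalize != "none":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    rank_deficient = bool(
        np.linalg.matrix_rank(M, tol=1e-10 * max(np.trace(M), 1.0)) < M.shape[0]
    )
    return CovFeature(
        matrix=M,
        n_bands=1,
        label=segment.label,
        session_id=segment.session_id,
        start=segment.start,
        trial_index=segment.trial_index,
        rank_deficient=rank_deficient,
    )


def multiband_covariance(
    segment: Segment,
    bands: BandSpec | list[tuple[float, float]],
    center: bool = True,
    normalize: str = "samples",
    order: int = 4,
) -> CovFeature:
    """Block-diagonal covariance across frequency bands.

    The k-th diagonal block is the covariance of the segment band-passed to
    band k; off-diagonal blocks are exactly zero.  A linear model on this
    matrix weights each band's spatial covariance independently, since the
    trace inner product of two block-diagonal matrices is the sum of the
    per-block inner products.
    """
    band_list = bands.bands if isinstance(bands, BandSpec) else list(bands)
    if not band_list:
        raise ValueError("at least one band required")
    blocks = []
    for band in band_list:
        filtered = replace(
            segment, data=bandpass_array(segment.data, band, segment.fs, order=order)
        )
        blocks.append(segment_covariance(filtered, center=center, normalize=normalize))
    M = linalg.block_diag(*[b.matrix for b in blocks])
    return CovFeature(
        matrix=M,
        n_bands=len(band_list),
        label=segment.label,
        session_id=segment.session_id,
        start=segment.start,
        trial_index=segment.trial_index,
        rank_deficient=any(b.rank_deficient for b in blocks),
    )


def extract_features(
    recordings: list[Recording],
    band: tuple[float, float] | None = (4.0, 47.0),
    bands: BandSpec | list[tuple[float, float]] | None = None,
    window_len: float = 5.0,
    step: float = 3.0,
    center: bool = True,
    normalize: str = "samples",
    order: int = 4,
) -> list[CovFeature]:
    """Full pipeline: filter trials, window them, covariance per window.

    Single-band mode (``band``, default 4-47 Hz wide band) filters each trial
    once; multi-band mode (``bands``) filters each trial per band and stacks
    per-window block-diagonal covariances.  Filtering always happens on the
    whole trial before windowing.
    """
    features: list[CovFeature] = []
    if bands is not None:
        band_list = bands.bands if isinstance(bands, BandSpec) else list(bands)
        for rec in recordings:
            per_band = [bandpass(rec, b, order=order) for b in band_list]
            windows_per_band = [
                sliding_windows(fr, window_len, step) for fr in per_band
            ]
            for win_tuple in zip(*windows_per_band):
                covs = [
                    segment_covariance(w, center=center, normalize=normalize)
                    for w in win_tuple
                ]
                ref = win_tuple[0]
                features.append(
                    CovFeature(
                        matrix=linalg.block_diag(*[c.matrix for c in covs]),
                        n_bands=len(band_list),
                        label=ref.label,
                        session_id=ref.session_id,
                        start=ref.start,
                        trial_index=ref.trial_index,
                        rank_deficient=any(c.rank_deficient for c in covs),
                    )
                )
    else:
        for rec in recordings:
            filtered = bandpass(rec, band, order=order) if band is not None else rec
            for seg in sliding_windows(filtered, window_len, step):
                features.append(
                    segment_covariance(seg, center=center, normalize=normalize)
                )
    return features


def save_features(path: str, features: list[CovFeature]) -> None:
    """Cache covariance features to an HDF5 file keyed by (session, trial, start)."""
    with h5py.File(path, "w") as f:
        for i, cf in enumerate(features):
            g = f.create_group(f"feature_{i:06d}")
            g.create_dataset("matrix", data=cf.matrix)
            g.attrs["n_bands"] = cf.n_bands
            g.attrs["label"] = 0 if cf.label is None else cf.label
            g.attrs["session_id"] = str(cf.session_id)
            g.attrs["start"] = cf.start
            g.attrs["trial_index"] = cf.trial_index


def load_features(path: str) -> list[CovFeature]:
    """Load covariance features cached by :func:`save_features`."""
    features = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            label = int(g.attrs["label"])
            sid: int | str = g.attrs["session_id"]
            try:
                sid = int(sid)
            except (TypeError, ValueError):
                sid = str(sid)
            features.append(
                CovFeature(
                    matrix=g["matrix"][()],
                    n_bands=int(g.attrs["n_bands"]),
                    label=None if label == 0 else label,
                    session_id=sid,
                    start=float(g.attrs["start"]),
                    trial_index=int(g.attrs["trial_index"]),
                )
            )
    return features
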