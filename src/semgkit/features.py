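"""The four per-channel sEMG features: MAV, RMS, WA and EC1.

Each feature is computed over sliding windows of the main feature
segment and averaged across windows:

* **MAV** — mean absolute value, ``(1/(n-1)) * sum |x|`` per window
  (the ``n-1`` normalisation is deliberate; ``mav_denominator="n"``
  restores the conventional ``1/n``);
* **RMS** — root mean square, ``sqrt(sum x^2 / (n-1))`` per window;
* **WA** — Willison amplitude, the count of consecutive-sample
  amplitude jumps ``|x_i - x_{i+1}|`` at or above a threshold;
* **EC1** — log10 of the mean per-window wavelet-packet coefficient
  energy (squared norm over all leaf nodes of a depth-``wp_level``
  packet decomposition), a compact time-frequency energy summary.

Window geometry defaults to the same 64/32 sliding convention used for
onset detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, SegmentError
from .io import Recording

FEATURE_NAMES = ("MAV", "RMS", "WA", "EC1")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for feature extraction: window length
    ``n_win`` and increment ``inc_win`` in samples."""

    n_win: int = 64
    inc_win: int = 32

    def __post_init__(self) -> None:
        if not (1 <= self.inc_win <= self.n_win):
            raise ConfigError(
                f"need 1 <= inc_win <= n_win, got inc_win={self.inc_win}, n_win={self.n_win}"
            )

    def window_count(self, n_samples: int) -> int:
        if n_samples < self.n_win:
            raise SegmentError(
                f"segment of {n_samples} samples shorter than window {self.n_win}"
            )
        return (n_samples - self.n_win) // self.inc_win + 1


@dataclass(frozen=True)
class FeatureConfig:
    """Feature parameters.

    ``wa_threshold`` is in signal amplitude units (default 1e-5 V =
    10 uV); it is independent of the segmentation energy threshold.
    ``wavelet``/``wp_level`` control the packet decomposition behind
    EC1; ``log_floor`` is the positive clamp inside the log10 so silent
    windows yield ``log10(log_floor)`` instead of ``-inf``.
    """

    wa_threshold: float = 1e-5
    wavelet: str = "db4"
    wp_level: int = 3
    log_floor: float = 1e-12
    mav_denominator: str = "n-1"

    def __post_init__(self) -> None:
        if self.wa_threshold < 0:
            raise ConfigError("wa_threshold must be >= 0")
        if self.wp_level < 1:
            raise ConfigError("wp_level must be >= 1")
        if not self.log_floor > 0:
            raise ConfigError("log_floor must be > 0")
        if self.mav_denominator not in ("n-1", "n"):
            raise ConfigError("mav_denominator must be 'n-1' or 'n'")


@dataclass
class ChannelFeatures:
    """The feature vector ``[MAV, RMS, WA, EC1]`` of one channel."""

    values: np.ndarray
    channel_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ConfigError(f"expected {len(FEATURE_NAMES)} feature values")
        if not np.isfinite(self.values).all():
            raise ConfigError("features must be finite")


def window_segment(x: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Cut a series into sliding windows along the last axis; returns
    shape ``(..., M_win, n_win)``. Same convention as frame_signal."""
    x = np.asarray(x, dtype=float)
    spec.window_count(x.shape[-1])
    return sliding_window_view(x, spec.n_win, axis=-1)[..., :: spec.inc_win, :]


def _check_windows(windows: np.ndarray, min_len: int = 2) -> np.ndarray:
    windows = np.asarray(windows, dtype=float)
    if windows.ndim < 2 or windows.shape[-2] < 1:
        raise SegmentError("need at least one window")
    if windows.shape[-1] < min_len:
        raise SegmentError(f"window length {windows.shape[-1]} < {min_len}")
    return windows


def mav(windows: np.ndarray, denominator: str = "n-1") -> float | np.ndarray:
    """Mean absolute value, averaged over windows."""
    windows = _check_windows(windows)
    n = windows.shape[-1]
    d = n - 1 if denominator == "n-1" else n
    return np.abs(windows).sum(axis=-1).mean(axis=-1) / d


def rms(windows: np.ndarray) -> float | np.ndarray:
    """Root mean square (``n-1`` denominator), averaged over windows."""
    windows = _check_windows(windows)
    n = windows.shape[-1]
    return np.sqrt(np.square(windows).sum(axis=-1) / (n - 1)).mean(axis=-1)


def wa(windows: np.ndarray, wa_threshold: float) -> float | np.ndarray:
    """Willison amplitude: per-window count of consecutive-sample jumps
    with magnitude >= ``wa_threshold``, averaged over windows."""
    windows = _check_windows(windows)
    jumps = np.abs(np.diff(windows, axis=-1)) >= wa_threshold
    return jumps.sum(axis=-1).mean(axis=-1).astype(float)


def wavelet_packet_energy(
    windows: np.ndarray, wavelet: str = "db4", level: int = 3, mode: str = "symmetric"
) -> np.ndarray:
    """Per-window wavelet-packet coefficient energy.

    Squared norm of the coefficients across all ``2**level`` leaf nodes
    of a full packet decomposition of each window. Implemented as a
    level-by-level batched DWT so arbitrarily many windows (and
    channels) are transformed in ``2**level - 1`` filter calls.
    """
    bands = [np.asarray(windows, dtype=float)]
    for _ in range(level):
        nxt = []
        for band in bands:
            ca, cd = pywt.dwt(band, wavelet, mode=mode, axis=-1)
            nxt.append(ca)
            nxt.append(cd)
        bands = nxt
    return sum(np.square(band).sum(axis=-1) for band in bands)


def ec1(windows: np.ndarray, config: FeatureConfig = FeatureConfig()) -> float | np.ndarray:
    """Log wavelet-packet energy: ``log10(mean_j |S_j|^2)`` where
    ``|S_j|^2`` is window ``j``'s packet coefficient energy, clamped
    below at ``log_floor``."""
    windows = _check_windows(windows, min_len=2**config.wp_level)
    energy = wavelet_packet_energy(windows, config.wavelet, config.wp_level)
    return np.log10(np.maximum(energy.mean(axis=-1), config.log_floor))


def extract_channel_features(
    segment: Recording,
    spec: WindowSpec = WindowSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> list[ChannelFeatures]:
    """Compute ``[MAV, RMS, WA, EC1]`` for every channel of a segment."""
    wins = window_segment(segment.data, spec)  # (n_channels, M_win, n_win)
    mat = np.column_stack(
        [
            mav(wins, config.mav_denominator),
            rms(wins),
            wa(wins, config.wa_threshold),
            ec1(wins, config),
        ]
    )
    return [ChannelFeatures(row, channel_index=i) for i, row in enumerate(mat)]


def feature_matrix(features: list[ChannelFeatures]) -> np.ndarray:
    """Stack per-channel feature vectors into an ``(n_channels, 4)`` array."""
    return np.vstack([f.values for f in features])


@dataclass
class FeatureScaler:
    """Per-feature affine map fitted on training data sending each
    feature's [min, max] to [-1, 1]; constant features map to 0."""

    center: np.ndarray
    half_range: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros_like(X)
        ok = self.half_range > 0
        out[:, ok] = (X[:, ok] - self.center[ok]) / self.half_range[ok]
        return out


def normalize_features(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, FeatureScaler]:
    """Scale each feature to (-1, 1) on the training data and apply the
    same map to the test data (test values may land outside the interval).

    A constant training feature is mapped to 0 everywhere and a warning
    is emitted.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ConfigError("empty training matrix")
    lo, hi = train.min(axis=0), train.max(axis=0)
    center = (hi + lo) / 2.0
    half_range = (hi - lo) / 2.0
    if (half_range == 0).any():
        idx = np.flatnonzero(half_range == 0)
        warnings.warn(
            f"constant training feature(s) at column(s) {idx.tolist()}; mapped to 0",
            stacklevel=2,
        )
    scaler = FeatureScaler(center=center, half_range=half_range)
    return scaler.transform(train), (None if test is None else scaler.transform(test)), scaler
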