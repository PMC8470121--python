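"""Onset detection and main-feature-segment extraction by frame energy.

The trial is cut into overlapping frames of ``L`` samples advancing by
``I`` samples (defaults 64/32 at 2 kHz). Each frame's energy is its sum
of squared amplitudes; the adaptive threshold ``th`` is the mean frame
energy (by default over the whole trial, whose frames are mostly rest;
optionally over a designated standing-rest prefix). The action onset
is the first frame of a run
of ``onset_run_length`` consecutive frames whose energy exceeds ``th``.
The main feature segment is the 2 s of signal starting 0.5 s after the
onset sample — the window that carries most of the action's energy,
skipping the movement-initiation transient.

Frame and sample indices in results are 1-based: frame ``FS`` starts at
sample ``SN = (FS-1)*I + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import ConfigError, NoOnsetError, SegmentError
from .io import Recording


@dataclass(frozen=True)
class FrameSpec:
    """Sliding-frame geometry: length ``L`` and increment ``I`` in samples.

    For a signal of ``N`` samples the frame count is
    ``M = floor((N - L)/I) + 1``; trailing samples that do not fill a
    whole frame are dropped, so ``(M-1)*I + L <= N < M*I + L``.
    """

    L: int = 64
    I: int = 32

    def __post_init__(self) -> None:
        if not (1 <= self.I <= self.L):
            raise ConfigError(f"need 1 <= I <= L, got I={self.I}, L={self.L}")

    def frame_count(self, n_samples: int) -> int:
        if n_samples < self.L:
            raise SegmentError(f"signal of {n_samples} samples shorter than frame length {self.L}")
        return (n_samples - self.L) // self.I + 1


@dataclass
class EnergyProfile:
    """Per-frame energies (squared-amplitude units) with the adaptive
    rest-derived threshold."""

    energies: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if (self.energies < 0).any() or self.threshold < 0:
            raise ConfigError("frame energies and threshold must be non-negative")


@dataclass(frozen=True)
class SegmentBounds:
    """1-based bounds of the main feature segment.

    ``FS`` — onset frame; ``SN`` — onset sample; ``MSN`` — segment start
    (0.5 s after onset); ``MEN`` — segment end (2.5 s after onset). The
    segment covers samples ``MSN .. MEN-1``, exactly ``2*fs`` of them.
    """

    FS: int
    SN: int
    MSN: int
    MEN: int
    fs: float


@dataclass(frozen=True)
class DenoiseConfig:
    """Pre-processing filter chain for raw sEMG.

    A 4th-order Butterworth high-pass removes baseline drift and DC, an
    IIR notch removes power-line interference, and per-channel soft
    wavelet thresholding (universal threshold, noise scale from the
    finest detail level) suppresses broadband noise. Applied with
    zero-phase (forward-backward) filtering.
    """

    highpass_hz: float = 10.0
    highpass_order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0
    wavelet: str = "db4"
    level: int = 4

    def __post_init__(self) -> None:
        if self.highpass_hz <= 0 or self.notch_hz <= 0:
            raise ConfigError("filter corner frequencies must be positive")


def denoise(rec: Recording, config: DenoiseConfig = DenoiseConfig()) -> Recording:
    """Filter out baseline drift, power-line interference and broadband noise.

    Returns a recording of identical shape. Raises :class:`ConfigError`
    when the sampling rate cannot support the configured corners.
    """
    nyq = rec.fs / 2
    if config.highpass_hz >= nyq or config.notch_hz >= nyq:
        raise ConfigError(
            f"fs={rec.fs} Hz too low for high-pass {config.highpass_hz} Hz / "
            f"notch {config.notch_hz} Hz"
        )
    x = rec.data
    # generous reflection padding: the notch's transient decays over
    # ~Q/(pi*f0) s, far longer than filtfilt's default pad
    padlen = min(rec.n_samples - 1, int(rec.fs))
    sos = sps.butter(config.highpass_order, config.highpass_hz, "highpass", fs=rec.fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
    b, a = sps.iirnotch(config.notch_hz, config.notch_q, fs=rec.fs)
    x = sps.filtfilt(b, a, x, axis=-1, padlen=padlen)
    x = _wavelet_denoise(x, config.wavelet, config.level)
    return rec.with_data(x)


def _wavelet_denoise(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    # Per-channel universal threshold sigma*sqrt(2 ln N); sigma from the
    # median absolute finest-level detail coefficient.
    n = x.shape[-1]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    level = min(level, max_level)
    if level < 1:
        return x
    coeffs = pywt.wavedec(x, wavelet, level=level, axis=-1)
    sigma = np.median(np.abs(coeffs[-1]), axis=-1, keepdims=True) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    out = [coeffs[0]]
    for d in coeffs[1:]:
        out.append(np.sign(d) * np.maximum(np.abs(d) - thr, 0.0))
    return pywt.waverec(out, wavelet, axis=-1)[..., :n]


def frame_signal(x: np.ndarray, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Cut a series into overlapping frames.

    ``x`` may be 1-D (samples) or 2-D (channels x samples); frames are
    taken along the last axis. Frame ``i`` (1-based) covers samples
    ``(i-1)*I+1 .. (i-1)*I+L``. Returns an array of shape
    ``(..., M, L)``; trailing samples not filling a frame are dropped.
    """
    x = np.asarray(x, dtype=float)
    spec.frame_count(x.shape[-1])  # validates length
    return sliding_window_view(x, spec.L, axis=-1)[..., :: spec.I, :]


def frame_energy(frames: np.ndarray) -> np.ndarray:
    """Per-frame total energy: the sum of squared amplitudes in the frame."""
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        raise SegmentError("no frames")
    return np.square(frames).sum(axis=-1)


def adaptive_threshold(rest_energies: np.ndarray) -> float:
    """Adaptive threshold ``th``: the mean frame energy at rest."""
    rest_energies = np.asarray(rest_energies, dtype=float)
    if rest_energies.size == 0:
        raise SegmentError("cannot derive a threshold from an empty rest energy series")
    return float(rest_energies.mean())


def energy_profile(
    rec: Recording,
    spec: FrameSpec = FrameSpec(),
    rest_seconds: float | None = None,
    per_channel: bool = False,
) -> EnergyProfile | list[EnergyProfile]:
    """Frame a recording and derive its energy profile and threshold.

    The default profile sums frame energies over channels so one onset is
    detected per trial; ``per_channel=True`` returns one profile per
    channel instead.

    With ``rest_seconds=None`` (default) the threshold is the mean
    energy over *all* frames of the trial: resting frames dominate the
    count, and action frames pull the mean well above the resting
    fluctuation band, so the threshold separates rest from action. A
    rest-only mean sits in the middle of the resting energy
    distribution, which chance runs of above-average rest frames cross
    constantly. Pass ``rest_seconds`` to average a designated standing-
    rest prefix instead (appropriate when a separate rest recording is
    prepended).
    """
    energies = frame_energy(frame_signal(rec.data, spec))  # (n_channels, M)
    if rest_seconds is None:
        m_rest = energies.shape[-1]
    else:
        n_rest = int(rest_seconds * rec.fs)
        # frames whose last sample (1-based (i-1)*I+L) falls inside the rest window
        m_rest = max((n_rest - spec.L) // spec.I + 1, 0)
        if m_rest < 1:
            raise SegmentError(
                f"rest window of {rest_seconds} s holds no complete frame (L={spec.L})"
            )
    if per_channel:
        return [EnergyProfile(e, adaptive_threshold(e[:m_rest])) for e in energies]
    total = energies.sum(axis=0)
    return EnergyProfile(total, adaptive_threshold(total[:m_rest]))


def detect_onset(profile: EnergyProfile, onset_run_length: int = 4) -> int:
    """First frame (1-based) of a run of ``onset_run_length`` consecutive
    frames with energy strictly above the threshold.

    The default run length of 4 requires the candidate frame and the
    next three to exceed ``th``; ``onset_run_length=3`` gives the laxer
    three-in-a-row variant. Raises :class:`NoOnsetError` when no
    qualifying run exists.
    """
    if onset_run_length < 1:
        raise ConfigError("onset_run_length must be >= 1")
    above = profile.energies > profile.threshold
    if len(above) < onset_run_length:
        raise NoOnsetError(
            f"profile has {len(above)} frames; need >= {onset_run_length}"
        )
    run = sliding_window_view(above, onset_run_length).all(axis=-1)
    hits = np.flatnonzero(run)
    if len(hits) == 0:
        raise NoOnsetError("no frame run exceeded the adaptive threshold")
    return int(hits[0]) + 1


def segment_bounds(FS: int, spec: FrameSpec, fs: float) -> SegmentBounds:
    """Main-feature-segment bounds for an onset at frame ``FS``:
    ``SN = (FS-1)*I + 1``, ``MSN = SN + round(0.5*fs)``,
    ``MEN = MSN + 2*fs`` (all 1-based samples)."""
    SN = (FS - 1) * spec.I + 1
    MSN = SN + int(round(0.5 * fs))
    MEN = MSN + int(round(2 * fs))
    return SegmentBounds(FS=FS, SN=SN, MSN=MSN, MEN=MEN, fs=fs)


def extract_main_segment(
    rec: Recording, FS: int, spec: FrameSpec = FrameSpec()
) -> tuple[Recording, SegmentBounds]:
    """Extract the 2 s main feature segment for an onset at frame ``FS``.

    The segment covers samples ``MSN .. MEN-1`` on every channel —
    exactly ``2*fs`` samples. Raises :class:`SegmentError` when the
    recording ends before ``MEN``.
    """
    b = segment_bounds(FS, spec, rec.fs)
    if b.MEN > rec.n_samples:
        raise SegmentError(
            f"recording too short after onset: segment end {b.MEN} > N={rec.n_samples}"
        )
    seg = rec.data[:, b.MSN - 1 : b.MEN - 1]
    return rec.with_data(seg), b


def segment_recording(
    rec: Recording,
    spec: FrameSpec = FrameSpec(),
    rest_seconds: float | None = None,
    onset_run_length: int = 4,
) -> tuple[Recording, SegmentBounds]:
    """Full chain on one trial: energy profile -> onset -> main segment."""
    profile = energy_profile(rec, spec, rest_seconds=rest_seconds)
    FS = detect_onset(profile, onset_run_length=onset_run_length)
    return extract_main_segment(rec, FS, spec)
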