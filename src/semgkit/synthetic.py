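"""Synthetic 8-channel lower-limb sEMG generator.

sEMG is modelled as amplitude-modulated band-limited Gaussian noise —
a standard statistical surrogate for the interference pattern of many
asynchronous motor-unit action potentials. Each trial is rest-level
noise throughout, plus an action burst whose per-channel amplitude is
a class-specific gain profile, with smooth raised-cosine onset/offset
ramps. The true onset sample is returned, so onset detection, channel
weighting and classification are all testable against ground truth.

Defaults emulate the reference acquisition protocol: 8 channels,
2 kHz sampling, 10 s trials (8 x 20,000 samples), signal band
10-500 Hz, six action classes. The default gain templates are the six
rows of the reference muscle-action correlation table rescaled to unit
mean, so the synthetic ground truth mirrors the printed muscle-action
structure; the burst amplitude scale (3 mV) is chosen so main-segment
absolute-amplitude sums land in the range of the reference energy
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .io import ACTION_LABELS, DatasetManifest, LabelledRecord, Recording
from .wfm import EnergyTable

#: Reference per-channel main-segment energy sums (absolute-amplitude
#: sums, volts) for one subject, six actions x eight channels.
REFERENCE_CHANNEL_ENERGIES = {
    "action1": (4.4075, 7.3995, 3.3853, 3.0290, 2.5047, 10.0337, 6.0779, 6.1198),
    "action2": (5.6125, 4.2509, 16.7769, 2.2035, 1.9899, 5.0036, 2.7665, 6.7932),
    "action3": (2.7713, 6.8533, 4.1197, 8.5512, 3.7452, 16.5496, 5.3684, 3.8048),
    "action4": (3.7745, 2.8812, 2.6002, 8.2039, 4.2894, 25.1282, 12.0314, 2.5562),
    "action5": (31.3369, 13.8150, 23.4856, 2.1398, 18.2272, 14.9905, 24.0917, 2.6756),
    "action6": (23.3024, 12.5947, 25.4307, 2.0793, 15.1958, 19.6991, 29.0533, 3.3588),
}

#: Reference muscle-action correlation coefficients (the channel
#: weights C_i derived from the energy table), six actions x eight
#: channels; each row sums to ~8.
REFERENCE_CORRELATIONS = {
    "action1": (0.8208, 1.3780, 0.6304, 0.5641, 0.4664, 1.8686, 1.1319, 1.1397),
    "action2": (0.9890, 0.7491, 2.9565, 0.3883, 0.3507, 0.8817, 0.4875, 1.1971),
    "action3": (0.4283, 1.0592, 0.6367, 1.3216, 0.5788, 2.5577, 0.8297, 0.5880),
    "action4": (0.4913, 0.3750, 0.3384, 1.0678, 0.5583, 3.2706, 1.5659, 0.3327),
    "action5": (1.9172, 0.8452, 1.4368, 0.1309, 1.1151, 0.9171, 1.4739, 0.1637),
    "action6": (1.4262, 0.7708, 1.5564, 0.1273, 0.9300, 1.2056, 1.7781, 0.2056),
}


def table2_fixture() -> dict[str, EnergyTable]:
    """The reference energy table as :class:`~semgkit.wfm.EnergyTable`
    rows, keyed ``action1..action6``."""
    return {k: EnergyTable(np.array(v)) for k, v in REFERENCE_CHANNEL_ENERGIES.items()}


@dataclass(frozen=True)
class SimConfig:
    """Acquisition-protocol parameters for one synthetic dataset."""

    n_per_class: int = 1
    fs: float = 2000.0
    duration: float = 10.0
    n_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_channels < 1:
            raise ConfigError("n_per_class and n_channels must be >= 1")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ConfigError(f"fs*duration must be a positive integer sample count, got {n}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass(frozen=True)
class ActionProfile:
    """Generative description of one action class.

    ``gains`` are per-channel burst amplitude multipliers (the class's
    muscle-activation pattern). The burst occupies
    ``[burst_onset, burst_onset + burst_duration]`` seconds with
    ``ramp``-second raised-cosine transitions. ``rest_noise_sd`` is the
    standing-rest noise level and ``burst_noise_sd`` the base burst
    amplitude (both in volts, before channel gain); ``band`` is the
    signal band in Hz.
    """

    gains: tuple[float, ...]
    burst_onset: float = 2.0
    burst_duration: float = 4.0
    rest_noise_sd: float = 1e-4
    burst_noise_sd: float = 3e-3
    band: tuple[float, float] = (10.0, 500.0)
    ramp: float = 0.05

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if (g < 0).any():
            raise ConfigError("gains must be >= 0")
        if not 0 < self.burst_onset:
            raise ConfigError("burst_onset must be > 0")
        if self.burst_duration <= 0:
            raise ConfigError("burst_duration must be > 0")
        if not 0 < self.band[0] < self.band[1]:
            raise ConfigError(f"invalid band {self.band}")


def default_profiles(
    burst_onset: float = 2.0, burst_duration: float = 4.0, **kwargs
) -> dict[str, ActionProfile]:
    """Six action profiles whose gain templates are the reference
    correlation rows rescaled to unit mean, keyed by label ``y1..y6``."""
    out = {}
    for label, action in zip(ACTION_LABELS, REFERENCE_CORRELATIONS):
        row = np.array(REFERENCE_CORRELATIONS[action])
        out[label] = ActionProfile(
            gains=tuple(row / row.mean()),
            burst_onset=burst_onset,
            burst_duration=burst_duration,
            **kwargs,
        )
    return out


def _band_noise(
    rng: np.random.Generator, shape: tuple[int, ...], band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    if band[1] >= fs / 2:
        raise ConfigError(f"band {band} exceeds Nyquist {fs / 2} Hz")
    sos = sps.butter(4, band, "bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def generate_recording(
    profile: ActionProfile, config: SimConfig, seed: int
) -> tuple[Recording, int]:
    """One synthetic trial; returns ``(recording, true_onset_sample)``
    with the onset as a 1-based sample index.

    The signal is ``rest_noise_sd * noise1 + gain_i * burst_noise_sd *
    envelope(t) * noise2`` per channel, with independent band-limited
    noises, so all-zero gains reduce exactly to rest.
    """
    if len(profile.gains) != config.n_channels:
        raise ConfigError(
            f"{len(profile.gains)} gains for {config.n_channels} channels"
        )
    if profile.burst_onset + profile.burst_duration > config.duration:
        raise ConfigError("burst extends past the end of the trial")
    rng = np.random.default_rng(seed)
    n, fs = config.n_samples, config.fs
    shape = (config.n_channels, n)
    rest = profile.rest_noise_sd * _band_noise(rng, shape, profile.band, fs)
    burst = _band_noise(rng, shape, profile.band, fs)
    t = np.arange(n) / fs
    env = _raised_cosine_envelope(
        t, profile.burst_onset, profile.burst_onset + profile.burst_duration, profile.ramp
    )
    gains = np.asarray(profile.gains)[:, None]
    data = rest + profile.burst_noise_sd * gains * env[None, :] * burst
    onset_sample = int(round(profile.burst_onset * fs)) + 1  # 1-based
    return Recording(data, fs=fs), onset_sample


def _raised_cosine_envelope(
    t: np.ndarray, start: float, stop: float, ramp: float
) -> np.ndarray:
    env = np.zeros_like(t)
    up = (t >= start) & (t < start + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    env[(t >= start + ramp) & (t <= stop - ramp)] = 1.0
    down = (t > stop - ramp) & (t <= stop)
    env[down] = 0.5 * (1 - np.cos(np.pi * (stop - t[down]) / ramp))
    return env


def generate_dataset(
    config: SimConfig, profiles: dict[str, ActionProfile] | None = None
) -> DatasetManifest:
    """``n_per_class`` labelled trials per action class.

    Per-trial seeds are derived deterministically from ``config.seed``;
    two master seeds give different datasets, one seed always the same.
    """
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(config.seed)
    records: list[LabelledRecord] = []
    for label in sorted(profiles):
        profile = profiles[label]
        for _ in range(config.n_per_class):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            rec, onset = generate_recording(profile, config, trial_seed)
            rec.label = label
            rec.subject_id = "sim"
            records.append(
                LabelledRecord(rec, label=label, subject_id="sim", true_onset=onset)
            )
    return DatasetManifest(records)
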