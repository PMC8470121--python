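"""Weighted feature method (WFM): energy-based channel weighting.

Muscles contribute unequally to a movement, and the per-channel
absolute-amplitude sum of the denoised signal is a proxy for that
contribution. Each channel's weight is

    C_i = n * sumabsX_i' / sumabsX,   i = 1..n,

its energy share rescaled so the weights sum to the channel count ``n``.
Scaling each channel's feature vector by its weight suppresses
channels that are quiet in the current movement (reducing redundancy
across channels) while amplifying the active ones (increasing
discrimination between movements).

Weights are computed per recording from that recording's own main
feature segment, so the transform is label-free and applicable at
prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateDataError, NoOnsetError, SegmentError
from .features import (
    ChannelFeatures,
    FeatureConfig,
    WindowSpec,
    extract_channel_features,
    feature_matrix,
)
from .io import DatasetManifest, Recording
from .segmentation import DenoiseConfig, FrameSpec, denoise, segment_recording


@dataclass
class EnergyTable:
    """Per-channel energies (absolute-amplitude sums) and their total."""

    energies: np.ndarray
    total: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if (self.energies < 0).any():
            raise ConfigError("channel energies must be >= 0")
        total = float(self.energies.sum())
        if self.total is None:
            self.total = total
        elif abs(self.total - total) > 1e-9 * max(total, 1.0):
            raise ConfigError(f"total {self.total} inconsistent with energy sum {total}")

    @property
    def n_channels(self) -> int:
        return len(self.energies)


@dataclass
class WeightVector:
    """Per-channel weights ``C_i``, dimensionless.

    Weights produced by :func:`channel_weights` sum to the channel
    count ``n``; arbitrary non-negative weights are accepted so callers
    can apply hand-chosen or unit weightings.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ConfigError("weights must be >= 0")


@dataclass
class FusionFeature:
    """The fused, channel-weighted feature vector.

    ``mode="concat"`` (default) concatenates the weighted per-channel
    vectors (dimension n*a); ``mode="sum"`` adds them (dimension a).
    """

    vector: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.isfinite(self.vector).all():
            raise ConfigError("fusion feature must be finite")


def channel_energies(rec: Recording, region: tuple[int, int] | None = None) -> EnergyTable:
    """Sum of absolute amplitudes per channel over a sample region.

    ``region`` is a 1-based half-open range ``(start, stop)`` (samples
    ``start .. stop-1``), e.g. ``(bounds.MSN, bounds.MEN)`` for the main
    feature segment; ``None`` uses the whole recording.
    """
    if region is None:
        sl = slice(None)
    else:
        start, stop = region
        if not (1 <= start < stop <= rec.n_samples + 1):
            raise ConfigError(f"region {region} outside [1, {rec.n_samples}]")
        sl = slice(start - 1, stop - 1)
    return EnergyTable(np.abs(rec.data[:, sl]).sum(axis=1))


def channel_weights(table: EnergyTable) -> WeightVector:
    """Energy shares rescaled to sum to the channel count:
    ``C_i = n * energies[i] / total``."""
    if table.total <= 0:
        raise DegenerateDataError("total channel energy is zero; weights undefined")
    return WeightVector(table.n_channels * table.energies / table.total)


def apply_weights(
    features: list[ChannelFeatures] | np.ndarray,
    weights: WeightVector,
    mode: str = "concat",
) -> FusionFeature:
    """Scale each channel's feature vector by its weight and fuse.

    ``concat`` keeps per-channel structure (dimension n*a); ``sum`` is
    the literal weighted sum over channels (dimension a).
    """
    mat = features if isinstance(features, np.ndarray) else feature_matrix(features)
    if mat.shape[0] != len(weights.weights):
        raise ConfigError(
            f"{mat.shape[0]} channel feature vectors vs {len(weights.weights)} weights"
        )
    weighted = mat * weights.weights[:, None]
    if mode == "concat":
        return FusionFeature(weighted.ravel(), mode)
    if mode == "sum":
        return FusionFeature(weighted.sum(axis=0), mode)
    raise ConfigError(f"unknown fusion mode {mode!r}")


@dataclass
class RecordFeatures:
    """Per-record intermediate products: the (n_channels, 4) feature
    matrix and the channel weight vector of one recording."""

    features: np.ndarray
    weights: WeightVector
    label: str


@dataclass
class FeatureDataset:
    """Fusion feature matrix with aligned labels and exclusion log."""

    X: np.ndarray
    y: np.ndarray
    kept_indices: list[int]
    excluded: list[tuple[int, str]] = field(default_factory=list)


def extract_record_features(
    manifest: DatasetManifest,
    frame_spec: FrameSpec = FrameSpec(),
    window_spec: WindowSpec = WindowSpec(),
    feature_config: FeatureConfig = FeatureConfig(),
    denoise_config: DenoiseConfig | None = DenoiseConfig(),
    rest_seconds: float | None = None,
    onset_run_length: int = 4,
) -> tuple[dict[int, RecordFeatures], list[tuple[int, str]]]:
    """Run denoise -> segment -> features -> weights on every record.

    Returns per-record features/weights keyed by manifest index, plus a
    list of ``(index, reason)`` for records excluded because no onset
    was found or the trial ended before the main segment.
    """
    out: dict[int, RecordFeatures] = {}
    excluded: list[tuple[int, str]] = []
    for i, rec in enumerate(manifest.records):
        r = rec.recording
        if denoise_config is not None:
            r = denoise(r, denoise_config)
        try:
            seg, bounds = segment_recording(
                r, frame_spec, rest_seconds=rest_seconds, onset_run_length=onset_run_length
            )
        except (NoOnsetError, SegmentError) as exc:
            excluded.append((i, str(exc)))
            continue
        weights = channel_weights(channel_energies(r, (bounds.MSN, bounds.MEN)))
        feats = feature_matrix(extract_channel_features(seg, window_spec, feature_config))
        out[i] = RecordFeatures(features=feats, weights=weights, label=rec.label)
    return out, excluded


def assemble_matrix(
    record_features: dict[int, RecordFeatures],
    indices: list[int] | None = None,
    use_wfm: bool = True,
    mode: str = "concat",
) -> FeatureDataset:
    """Stack per-record fusion vectors into a design matrix.

    ``use_wfm=False`` skips the channel weighting (the ablation arm):
    channels are fused with unit weights.
    """
    if indices is None:
        indices = sorted(record_features)
    rows, labels, kept = [], [], []
    for i in indices:
        if i not in record_features:
            continue
        rf = record_features[i]
        w = rf.weights if use_wfm else WeightVector(np.ones(rf.features.shape[0]))
        rows.append(apply_weights(rf.features, w, mode).vector)
        labels.append(rf.label)
        kept.append(i)
    if not rows:
        raise DegenerateDataError("no usable records")
    return FeatureDataset(np.vstack(rows), np.asarray(labels), kept)


def build_dataset(
    manifest: DatasetManifest,
    frame_spec: FrameSpec = FrameSpec(),
    window_spec: WindowSpec = WindowSpec(),
    feature_config: FeatureConfig = FeatureConfig(),
    mode: str = "concat",
    use_wfm: bool = True,
    denoise_config: DenoiseConfig | None = DenoiseConfig(),
    rest_seconds: float | None = None,
) -> FeatureDataset:
    """Full feature pipeline over a manifest: one fusion row per record,
    ordered as the manifest, with failed records excluded and logged."""
    if len(manifest) == 0:
        raise ConfigError("empty manifest")
    rf, excluded = extract_record_features(
        manifest, frame_spec, window_spec, feature_config, denoise_config, rest_seconds
    )
    ds = assemble_matrix(rf, indices=list(range(len(manifest))), use_wfm=use_wfm, mode=mode)
    ds.excluded = excluded
    return ds
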