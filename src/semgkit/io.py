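"""Reading, writing and splitting multichannel sEMG trials.

A trial is a channels x samples amplitude matrix (volts) with a sampling
rate. Recordings are stored on disk as plain CSV, one column per channel,
with an optional single header row of channel labels (auto-detected: a
non-numeric first row is treated as the header). Sample indices reported
to users are 1-based, matching the convention of the segmentation
formulas; internal numpy storage is 0-based.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

#: Electrode placement of the default 8-channel lower-limb montage:
#: right then left leg, each rectus femoris, biceps femoris, tibialis
#: anterior, gastrocnemius.
DEFAULT_CHANNEL_LABELS = (
    "R_rectus_femoris",
    "R_biceps_femoris",
    "R_tibialis_anterior",
    "R_gastrocnemius",
    "L_rectus_femoris",
    "L_biceps_femoris",
    "L_tibialis_anterior",
    "L_gastrocnemius",
)

#: The six lower-limb action classes.
ACTION_LABELS = ("y1", "y2", "y3", "y4", "y5", "y6")

#: Human-readable meaning of each action label.
ACTION_DESCRIPTIONS = {
    "y1": "raise right leg",
    "y2": "lower right leg",
    "y3": "raise left leg",
    "y4": "lower left leg",
    "y5": "sitting to standing",
    "y6": "standing to sitting",
}


@dataclass
class Recording:
    """One multichannel sEMG trial.

    Parameters
    ----------
    data
        Amplitude matrix of shape ``(n_channels, n_samples)``, in volts
        (or consistent arbitrary amplitude units; no conversion is done).
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered muscle names, one per channel. Defaults to the 8-channel
        lower-limb montage when the channel count matches, else
        ``CH1..CHn``.
    label
        Optional action class (one of ``y1..y6``).
    subject_id
        Optional subject identifier.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] | None = None
    label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError(
                f"recording data must be 2-D (channels x samples), got ndim={self.data.ndim}"
            )
        n_ch, n = self.data.shape
        if n_ch < 1 or n < 1:
            raise ConfigError(f"recording must have >=1 channel and >=1 sample, got {n_ch}x{n}")
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_labels is None:
            if n_ch == len(DEFAULT_CHANNEL_LABELS):
                self.channel_labels = DEFAULT_CHANNEL_LABELS
            else:
                self.channel_labels = tuple(f"CH{i + 1}" for i in range(n_ch))
        else:
            self.channel_labels = tuple(self.channel_labels)
            if len(self.channel_labels) != n_ch:
                raise ConfigError(
                    f"{len(self.channel_labels)} channel labels for {n_ch} channels"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with the amplitude matrix replaced."""
        return dataclasses.replace(self, data=data)


def _first_row_is_header(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for cell in first.strip().split(","):
        try:
            float(cell)
        except ValueError:
            return True
    return False


def read_recording(
    path: str | Path,
    fs: float,
    labels: tuple[str, ...] | None = None,
    label: str | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a CSV trial (one column per channel) into a :class:`Recording`.

    A non-numeric first row is treated as a header of channel labels.
    Raises :class:`FormatError` naming the offending row/column on
    non-numeric cells or ragged rows.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    header = _first_row_is_header(path)
    try:
        df = pd.read_csv(path, header=0 if header else None, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed CSV ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() != df[col].isna())[0])
            raise FormatError(
                f"{path}: non-numeric cell at data row {row + 1}, column {j + 1}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(f"{path}: missing value at data row {i + 1}, column {j + 1}")
    if labels is None and header:
        labels = tuple(str(c) for c in df.columns)
    return Recording(values.T, fs=fs, channel_labels=labels, label=label, subject_id=subject_id)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV (header of channel labels, one column per
    channel, full float precision so a round-trip is lossless)."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, index=False)


@dataclass
class LabelledRecord:
    """One dataset entry: a recording with its class label and metadata."""

    recording: Recording
    label: str
    subject_id: str | None = None
    true_onset: int | None = None  # 1-based sample index, known for synthetic data


@dataclass
class DatasetManifest:
    """An ordered collection of labelled recordings with an optional
    train/test split (``split[i]`` is ``"train"`` or ``"test"``)."""

    records: list[LabelledRecord]
    split: list[str] | None = None

    def __post_init__(self) -> None:
        if self.split is not None and len(self.split) != len(self.records):
            raise ConfigError("split length must match record count")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def indices(self, part: str) -> list[int]:
        if self.split is None:
            raise ConfigError("manifest has no split; call split_dataset first")
        return [i for i, s in enumerate(self.split) if s == part]

    def subset(self, part: str) -> "DatasetManifest":
        idx = self.indices(part)
        return DatasetManifest([self.records[i] for i in idx])


def split_dataset(manifest: DatasetManifest, fraction: float, seed: int) -> DatasetManifest:
    """Assign each record to the training or test set, stratified by class.

    Per class, ``round(fraction * count)`` records go to training (within
    one record of the requested fraction); the assignment is a uniform
    seeded shuffle, deterministic for a fixed seed. Each class must have
    at least 2 records.
    """
    if not 0 < fraction <= 1:
        raise ConfigError(f"training fraction must be in (0, 1], got {fraction}")
    labels = np.asarray(manifest.labels)
    rng = np.random.default_rng(seed)
    split = [""] * len(manifest)
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ConfigError(f"class {cls!r} has {len(idx)} record(s); need >=2 to split")
        idx = rng.permutation(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx))
        for i in idx[:n_train]:
            split[i] = "train"
        for i in idx[n_train:]:
            split[i] = "test"
    return DatasetManifest(manifest.records, split=split)


def save_manifest(manifest: DatasetManifest, outdir: str | Path, fs: float | None = None) -> Path:
    """Write each recording as CSV plus a ``manifest.json`` index.

    The JSON lists, per record: file path, label, subject, sampling rate,
    split assignment and (for synthetic data) the true onset sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(manifest.records):
        fname = f"trial_{i:05d}_{rec.label}.csv"
        write_recording(rec.recording, outdir / fname)
        entries.append(
            {
                "path": fname,
                "label": rec.label,
                "subject_id": rec.subject_id,
                "fs": rec.recording.fs,
                "true_onset": rec.true_onset,
                "split": manifest.split[i] if manifest.split else None,
            }
        )
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump({"records": entries}, fh, indent=1)
    return mpath


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load a dataset written by :func:`save_manifest`."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    base = path.parent
    records, split = [], []
    for e in doc["records"]:
        rec = read_recording(base / e["path"], fs=e["fs"], label=e["label"],
                             subject_id=e.get("subject_id"))
        records.append(
            LabelledRecord(rec, label=e["label"], subject_id=e.get("subject_id"),
                           true_onset=e.get("true_onset"))
        )
        split.append(e.get("split"))
    has_split = all(s in ("train", "test") for s in split)
    return DatasetManifest(records, split=split if has_split else None)
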