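"""Reading and writing of recordings, hypnograms and event annotations.

All internal coordinates are 0-based half-open sample intervals.  On disk,
event annotations are expressed in seconds (millisecond precision), one
event per row of a comma-delimited file with a header.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: The three segment classes handled downstream.
EVENT_LABELS = ("saccade", "blink", "artifact")

#: Sleep-stage codes accepted in hypnograms.
STAGE_CODES = ("W", "N1", "N2", "N3", "REM")


@dataclass
class Recording:
    """A multichannel signal with a common sampling rate.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel amplitudes, typically microvolts (or z-units after
        preprocessing).
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_labels : list of str
        One label per channel.
    start_time : optional
        Recording start timestamp, if known.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: object | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] == 0 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("need at least one channel and one label per channel")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, label_substring: str = "EOG1") -> np.ndarray:
        """Return the first channel whose label contains ``label_substring``.

        Falls back to the first channel when no label matches; the analysis
        channel of the detection pipeline is the supra-orbital EOG1 lead.
        """
        for i, lab in enumerate(self.channel_labels):
            if label_substring.lower() in lab.lower():
                return self.samples[i]
        return self.samples[0]


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels over a night."""

    stages: list[str]
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if len(self.stages) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(self.stages) - set(STAGE_CODES)
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(bad)}")


@dataclass(frozen=True)
class REMInterval:
    """Half-open sample interval [start, end) of one continuous REM bout."""

    start: int
    end: int
    recording_fs: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.recording_fs


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled event in seconds from recording start."""

    onset_s: float
    offset_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("onset must precede offset")
        if self.label not in EVENT_LABELS:
            raise ValueError(f"label must be one of {EVENT_LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def read_recording(path: str | Path, format: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from an EDF file or a delimited-text signal file.

    CSV files carry one header row of channel names and one column per
    channel; the sampling rate must then be supplied via ``fs``.  EDF files
    are read through :mod:`mne` and carry their own rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        # mne rescales EDF voltages to SI units; keep amplitudes as stored.
        return Recording(
            samples=raw.get_data(units=None),
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            start_time=raw.info.get("meas_date"),
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    if fs is None:
        raise ValueError("sampling rate fs is required for csv recordings")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header:
            raise ValueError(f"{path}: empty file")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}")
            rows.append([float(v) for v in row])
    if not rows:
        raise ValueError(f"{path}: no samples")
    return Recording(samples=np.asarray(rows, dtype=float).T, fs=fs, channel_labels=list(header))


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as delimited text: header of channel names, one row per sample."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(rec.channel_labels)
        for row in rec.samples.T:
            w.writerow([f"{v:.6f}" for v in row])


def read_hypnogram(path: str | Path, epoch_s: float = 30.0) -> Hypnogram:
    """Read a hypnogram: one stage code (W/N1/N2/N3/REM) per line."""
    stages = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return Hypnogram(stages=stages, epoch_s=epoch_s)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(h.stages) + "\n")


def extract_rem_intervals(h: Hypnogram, fs: float) -> list[REMInterval]:
    """Convert maximal runs of consecutive REM epochs to sample intervals.

    Each interval spans whole epochs, expressed as 0-based half-open sample
    indices at rate ``fs``.  Returns an empty list when the night contains
    no REM.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    samples_per_epoch = h.epoch_s * fs
    intervals: list[REMInterval] = []
    run_start: int | None = None
    for i, stage in enumerate(list(h.stages) + ["W"]):  # sentinel closes a trailing run
        if stage == "REM" and run_start is None:
            run_start = i
        elif stage != "REM" and run_start is not None:
            intervals.append(
                REMInterval(
                    start=int(round(run_start * samples_per_epoch)),
                    end=int(round(i * samples_per_epoch)),
                    recording_fs=fs,
                )
            )
            run_start = None
    return intervals


def read_events(path: str | Path) -> list[EventAnnotation]:
    """Read annotations from delimited text with columns onset_s, offset_s, label."""
    events: list[EventAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"onset_s", "offset_s", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns onset_s, offset_s, label")
        for row in reader:
            events.append(
                EventAnnotation(
                    onset_s=float(row["onset_s"]),
                    offset_s=float(row["offset_s"]),
                    label=row["label"].strip(),
                )
            )
    return events


def write_events(events: Sequence[EventAnnotation], path: str | Path) -> None:
    """Write annotations at millisecond precision; round-trips through read_events."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "offset_s", "label"])
        for ev in events:
            w.writerow([f"{ev.onset_s:.3f}", f"{ev.offset_s:.3f}", ev.label])
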