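"""Recording and beat-annotation containers, CSV I/O, and resampling.

The canonical on-disk recording format is a plain CSV with a header row
(``time_ms`` column optional, one column per channel) plus a sampling rate
declared by the caller.  Beat annotations are two-column CSVs
(``time_ms,label``).  All event times throughout the package are
milliseconds from recording start; sample index ``i`` maps to time
``i / fs * 1000``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeatLabel",
    "BeatSeries",
    "Recording",
    "read_beats",
    "read_recording",
    "resample_linear",
    "write_beats",
    "write_recording",
]

_TIME_COLUMN = "time_ms"
_FLOAT_FORMAT = "%.12g"


class BeatLabel(str, enum.Enum):
    """Provenance of a beat-time series."""

    R_PEAK = "R_PEAK"
    NCC_PEAK = "NCC_PEAK"
    GROUND_TRUTH = "GROUND_TRUTH"


@dataclass
class Recording:
    """Uniformly sampled multi-channel physiological recording.

    Parameters
    ----------
    channels
        Mapping of channel label to 1-D sample array (mV for ECG,
        deg/s for gyroscope channels).  All channels must have equal length
        and finite values.
    fs
        Sampling rate in Hz, strictly positive.
    start_time
        Offset of the first sample in ms (default 0).
    meta
        Free-form subject/source tags.
    """

    channels: dict[str, np.ndarray]
    fs: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }
        lengths = {name: x.shape for name, x in self.channels.items()}
        first_name, first_shape = next(iter(lengths.items()))
        if len(first_shape) != 1:
            raise ValueError(f"channel {first_name!r} is not 1-D")
        for name, shape in lengths.items():
            if shape != first_shape:
                raise ValueError(
                    f"channel {name!r} has length {shape[0]}, "
                    f"expected {first_shape[0]} (as {first_name!r})"
                )
        for name, x in self.channels.items():
            if not np.all(np.isfinite(x)):
                raise ValueError(f"channel {name!r} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def duration_ms(self) -> float:
        """Span (n_samples - 1) / fs in ms."""
        return (self.n_samples - 1) / self.fs * 1000.0

    def times_ms(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs * 1000.0


@dataclass
class BeatSeries:
    """Ordered event times in ms with a provenance label.

    ``times`` must be strictly increasing and non-negative; an empty series
    is valid (e.g. no beats detected on a flat signal).
    """

    times: np.ndarray
    label: BeatLabel = BeatLabel.R_PEAK

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.label = BeatLabel(self.label)
        if self.times.ndim != 1:
            raise ValueError("beat times must be 1-D")
        if self.times.size:
            if not np.all(np.isfinite(self.times)):
                raise ValueError("beat times must be finite")
            if np.any(self.times < 0):
                raise ValueError("beat times must be non-negative")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def read_recording(
    path: str | Path,
    fs: float,
    channels: Sequence[str] | Mapping[str, str] | None = None,
) -> Recording:
    """Read a CSV recording with a declared sampling rate.

    ``channels`` selects (and optionally renames, if a mapping of
    ``csv_column -> channel_label``) the columns to load; by default every
    column except ``time_ms`` is taken as a channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    available = [c for c in frame.columns if c != _TIME_COLUMN]
    if channels is None:
        mapping = {c: c for c in available}
    elif isinstance(channels, Mapping):
        mapping = dict(channels)
    else:
        mapping = {c: c for c in channels}
    out: dict[str, np.ndarray] = {}
    for column, label in mapping.items():
        if column not in frame.columns:
            raise ValueError(
                f"requested channel {column!r} not found in {path.name} "
                f"(available: {available})"
            )
        out[label] = frame[column].to_numpy(dtype=float)
    return Recording(channels=out, fs=fs, meta={"source": str(path)})


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as ``time_ms,<channel...>`` CSV (12 significant digits)."""
    frame = pd.DataFrame({_TIME_COLUMN: rec.times_ms(), **rec.channels})
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def resample_linear(rec: Recording, target_fs: float) -> Recording:
    """Linearly interpolate every channel onto a uniform grid at ``target_fs``.

    The new grid is ``t_k = k / target_fs`` for ``k = 0..floor(duration *
    target_fs)``; no extrapolation beyond the original support occurs, so
    the first and last samples of every channel are preserved.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs < rec.fs:
        raise ValueError(
            f"target_fs {target_fs} Hz is below the recording rate {rec.fs} Hz; "
            "only upsampling is supported"
        )
    if target_fs == rec.fs:
        return Recording(
            channels={k: v.copy() for k, v in rec.channels.items()},
            fs=rec.fs,
            start_time=rec.start_time,
            meta=dict(rec.meta),
        )
    n = rec.n_samples
    t_old = np.arange(n) / rec.fs
    duration = (n - 1) / rec.fs
    n_new = int(np.floor(duration * target_fs)) + 1
    t_new = np.arange(n_new) / target_fs
    # guard the final grid point against float overshoot of the support
    t_new = np.minimum(t_new, duration)
    channels = {
        name: np.interp(t_new, t_old, x) for name, x in rec.channels.items()
    }
    return Recording(
        channels=channels, fs=target_fs, start_time=rec.start_time, meta=dict(rec.meta)
    )


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    """Write a beat series as a ``time_ms,label`` CSV (header always present)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_ms,label\n")
        for t in beats.times:
            fh.write(f"{float(t)!r},{beats.label.value}\n")


def read_beats(path: str | Path) -> BeatSeries:
    """Read a beat series written by :func:`write_beats`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        return BeatSeries(times=np.empty(0), label=BeatLabel.R_PEAK)
    labels = frame["label"].unique()
    if len(labels) != 1:
        raise ValueError(f"mixed labels in {path}: {sorted(labels)}")
    return BeatSeries(
        times=frame[_TIME_COLUMN].to_numpy(dtype=float), label=BeatLabel(labels[0])
    )
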