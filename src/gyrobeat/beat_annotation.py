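"""ECG-referenced classification of detected beats into TP/FP/FN/DE.

Reference R peaks partition the recording into cardiac cycles
(half-open R-to-R windows).  Within each cycle:

* no NCC peak                         -> false negative (FN)
* a peak near the expected mechanical
  delay after the R peak              -> true positive (TP);
  any further peaks in the cycle      -> false positives (FP)
* only temporally implausible peaks   -> detection error (DE)

A DE cycle holds a single spurious detection and no true one, so it
enters both the sensitivity and the PPV denominators; the FP tally here
counts only *extra* in-cycle peaks, matching the convention in which
total detections = TP + FP + DE.

"Implausible" is operationalized as: nearest peak further than
``delay_tol_ms`` (default 150 ms) from the expected position
``R_j + expected_delay_ms``, where the expected delay is, by default,
the median signed offset between each cycle's R peak and its nearest
NCC peak over the whole record.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .signal_io import BeatSeries

__all__ = [
    "CycleAnnotation",
    "CycleLabel",
    "DetectionCounts",
    "IBIPairs",
    "annotate",
    "cycle_windows",
    "estimate_expected_delay",
    "inter_beat_intervals",
    "pair_valid_ibis",
]

DEFAULT_DELAY_TOL_MS = 150.0


class CycleLabel(str, enum.Enum):
    TP = "TP"
    FN = "FN"
    DE = "DE"


@dataclass(frozen=True)
class DetectionCounts:
    """TP/FP/FN/DE tallies.  FP counts extra in-cycle peaks only; the DE
    term is added to the metric denominators separately."""

    TP: int
    FP: int
    FN: int
    DE: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "DE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cycles(self) -> int:
        return self.TP + self.FN + self.DE

    @property
    def n_detections(self) -> int:
        """Total detections attributed to cycles: TP + FP + DE."""
        return self.TP + self.FP + self.DE


@dataclass
class CycleAnnotation:
    """Per-cycle classification record."""

    window_ms: tuple[float, float]  # half-open [start, end)
    peaks_ms: np.ndarray
    label: CycleLabel
    matched_ms: float | None  # TP peak time, if any
    extra_fp: int  # in-cycle peaks beyond the matched/spurious one


@dataclass
class IBIPairs:
    """Element-wise paired reference/test inter-beat intervals (ms)."""

    ref_ibi: np.ndarray
    test_ibi: np.ndarray

    def __post_init__(self) -> None:
        self.ref_ibi = np.asarray(self.ref_ibi, dtype=float)
        self.test_ibi = np.asarray(self.test_ibi, dtype=float)
        if self.ref_ibi.shape != self.test_ibi.shape:
            raise ValueError("ref/test interval arrays must have equal length")
        if self.ref_ibi.size and (
            np.any(self.ref_ibi <= 0) or np.any(self.test_ibi <= 0)
        ):
            raise ValueError("inter-beat intervals must be positive")

    def __len__(self) -> int:
        return self.ref_ibi.size


def cycle_windows(
    rpeaks: BeatSeries, offset_ms: float = 0.0
) -> list[tuple[float, float]]:
    """Half-open cardiac-cycle windows ``[R_j + d, R_{j+1} + d)``."""
    if len(rpeaks) < 2:
        raise ValueError("need at least 2 R peaks to form cycle windows")
    t = rpeaks.times + offset_ms
    return [(float(a), float(b)) for a, b in zip(t[:-1], t[1:])]


def estimate_expected_delay(
    ncc_peaks: BeatSeries, rpeaks: BeatSeries, offset_ms: float = 0.0
) -> float:
    """Median signed offset between each cycle's R peak and its nearest
    in-cycle NCC peak; 0.0 when no cycle contains a peak."""
    offsets = []
    for j, (lo, hi) in enumerate(cycle_windows(rpeaks, offset_ms)):
        in_cycle = ncc_peaks.times[(ncc_peaks.times >= lo) & (ncc_peaks.times < hi)]
        if in_cycle.size:
            r = rpeaks.times[j]
            offsets.append(in_cycle[np.argmin(np.abs(in_cycle - r))] - r)
    return float(np.median(offsets)) if offsets else 0.0


def annotate(
    ncc_peaks: BeatSeries,
    rpeaks: BeatSeries,
    expected_delay_ms: float | None = None,
    delay_tol_ms: float = DEFAULT_DELAY_TOL_MS,
    offset_ms: float = 0.0,
) -> tuple[list[CycleAnnotation], DetectionCounts]:
    """Classify every cardiac cycle and tally detection counts.

    ``expected_delay_ms=None`` estimates the R-to-beat delay from the
    data via :func:`estimate_expected_delay`.
    """
    windows = cycle_windows(rpeaks, offset_ms)
    if expected_delay_ms is None:
        expected_delay_ms = estimate_expected_delay(ncc_peaks, rpeaks, offset_ms)

    annotations: list[CycleAnnotation] = []
    tp = fp = fn = de = 0
    for j, (lo, hi) in enumerate(windows):
        in_cycle = ncc_peaks.times[(ncc_peaks.times >= lo) & (ncc_peaks.times < hi)]
        if in_cycle.size == 0:
            annotations.append(
                CycleAnnotation((lo, hi), in_cycle, CycleLabel.FN, None, 0)
            )
            fn += 1
            continue
        expected = rpeaks.times[j] + expected_delay_ms
        k = int(np.argmin(np.abs(in_cycle - expected)))
        extra = int(in_cycle.size - 1)
        fp += extra
        if abs(in_cycle[k] - expected) <= delay_tol_ms:
            annotations.append(
                CycleAnnotation((lo, hi), in_cycle, CycleLabel.TP,
                                float(in_cycle[k]), extra)
            )
            tp += 1
        else:
            annotations.append(
                CycleAnnotation((lo, hi), in_cycle, CycleLabel.DE, None, extra)
            )
            de += 1
    return annotations, DetectionCounts(TP=tp, FP=fp, FN=fn, DE=de)


def inter_beat_intervals(beats: BeatSeries) -> np.ndarray:
    """First differences of beat times in ms (length n-1)."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to form intervals")
    return np.diff(beats.times)


def pair_valid_ibis(
    annotations: list[CycleAnnotation], rpeaks: BeatSeries
) -> IBIPairs:
    """Build paired reference/test intervals over consecutive TP cycles.

    The interval pair (R_j -> R_{j+1}, matched peak_j -> matched peak_{j+1})
    is emitted iff cycles j and j+1 are both TP; intervals touching FN or
    DE cycles are discarded, and extra FP peaks never enter interval
    construction.
    """
    ref: list[float] = []
    test: list[float] = []
    for j in range(len(annotations) - 1):
        a, b = annotations[j], annotations[j + 1]
        if a.label is CycleLabel.TP and b.label is CycleLabel.TP:
            ref.append(float(rpeaks.times[j + 1] - rpeaks.times[j]))
            test.append(b.matched_ms - a.matched_ms)
    return IBIPairs(ref_ibi=np.asarray(ref), test_ibi=np.asarray(test))
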