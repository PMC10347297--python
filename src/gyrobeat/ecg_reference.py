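"""Reference R-peak detection on the preprocessed ECG (Pan-Tompkins).

Classic stages: 5-15 Hz band-pass to enhance the QRS, five-point
derivative, squaring, 150 ms moving-window integration, then dual
adaptive signal/noise thresholds with search-back, a 200 ms refractory
period and a 360 ms slope-based T-wave rejection.  The derivative and
integration kernels are applied symmetrically (centred) and the
band-pass is zero-phase, so integrated-signal fiducials stay aligned
with the QRS; each accepted fiducial is finally refined to the local
maximum of the band-passed ECG within +/-40 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .signal_io import BeatLabel, BeatSeries

__all__ = ["PTState", "pan_tompkins", "refine_rpeaks"]


@dataclass(frozen=True)
class PTState:
    """Tunable constants of the detector (classic published values)."""

    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    integration_window_ms: float = 150.0
    refractory_ms: float = 200.0
    twave_window_ms: float = 360.0
    twave_slope_ratio: float = 0.5
    searchback_rr_factor: float = 1.66
    refine_window_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.integration_window_ms <= 0:
            raise ValueError("integration window must be positive")
        if self.refractory_ms < 0:
            raise ValueError("refractory period must be non-negative")


def _centered_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-length convolution with the kernel centre aligned to each sample."""
    return np.convolve(x, kernel, mode="same")


def _stages(ecg: np.ndarray, fs: float, state: PTState):
    """Band-passed ECG, squared derivative, and moving-window integration."""
    sos = signal.butter(
        3, [state.band_low_hz, state.band_high_hz], btype="bandpass", fs=fs, output="sos"
    )
    bp = signal.sosfiltfilt(sos, ecg)
    # five-point derivative; antisymmetric kernel keeps zero group delay
    deriv_kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = _centered_convolve(bp, deriv_kernel[::-1])
    squared = deriv**2
    win = max(1, int(round(state.integration_window_ms / 1000.0 * fs)))
    mwi = _centered_convolve(squared, np.ones(win) / win)
    return bp, squared, mwi


def pan_tompkins(ecg: np.ndarray, fs: float, state: PTState | None = None) -> BeatSeries:
    """Detect R peaks; returns strictly increasing times in ms.

    A flat (or beat-free) signal yields an empty series; a signal shorter
    than 2 s raises ``ValueError``.
    """
    state = state or PTState()
    ecg = np.asarray(ecg, dtype=float)
    if fs < 200:
        raise ValueError(f"Pan-Tompkins expects fs >= 200 Hz, got {fs}")
    if ecg.size < 2 * fs:
        raise ValueError(
            f"signal of {ecg.size} samples (< 2 s at fs={fs}) too short for "
            "R-peak detection"
        )
    bp, squared, mwi = _stages(ecg, fs, state)
    if np.ptp(mwi) == 0:
        return BeatSeries(times=np.empty(0), label=BeatLabel.R_PEAK)

    refractory = max(1, int(round(state.refractory_ms / 1000.0 * fs)))
    candidates, _ = signal.find_peaks(mwi, distance=refractory)
    if candidates.size == 0:
        return BeatSeries(times=np.empty(0), label=BeatLabel.R_PEAK)

    # threshold initialisation from the first two seconds
    head = slice(0, int(2 * fs))
    spki = 0.25 * float(np.max(mwi[head]))
    npki = 0.5 * float(np.mean(mwi[head]))

    twave_span = int(round(state.twave_window_ms / 1000.0 * fs))
    slope_half = max(1, int(round(0.075 * fs)))  # slope assessed over ~75 ms

    def local_slope(idx: int) -> float:
        lo = max(0, idx - slope_half)
        hi = min(squared.size, idx + slope_half + 1)
        return float(np.max(squared[lo:hi]))

    qrs: list[int] = []
    rr_history: list[float] = []
    pending_noise: list[int] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    def accept(idx: int, searchback: bool = False) -> None:
        nonlocal spki
        gain = 0.25 if searchback else 0.125
        spki = gain * float(mwi[idx]) + (1 - gain) * spki
        if qrs:
            rr_history.append(idx - qrs[-1])
            if len(rr_history) > 8:
                rr_history.pop(0)
        qrs.append(idx)
        pending_noise.clear()

    for idx in candidates:
        peak = float(mwi[idx])
        is_qrs = peak > threshold()
        if is_qrs and qrs and (idx - qrs[-1]) < twave_span:
            # T wave: comparable timing but much shallower slope than last QRS
            if local_slope(idx) < state.twave_slope_ratio * local_slope(qrs[-1]):
                is_qrs = False
        if is_qrs:
            accept(idx)
        else:
            npki = 0.125 * peak + 0.875 * npki
            pending_noise.append(idx)
        # search-back when an expected beat seems missed
        if qrs and rr_history:
            rr_avg = float(np.mean(rr_history))
            if (idx - qrs[-1]) > state.searchback_rr_factor * rr_avg:
                window = [
                    j
                    for j in pending_noise
                    if qrs[-1] + refractory <= j <= idx - refractory
                ]
                if window:
                    best = max(window, key=lambda j: mwi[j])
                    if mwi[best] > 0.5 * threshold():
                        accept(best, searchback=True)

    if not qrs:
        return BeatSeries(times=np.empty(0), label=BeatLabel.R_PEAK)
    qrs.sort()
    coarse = BeatSeries(
        times=np.asarray(qrs, dtype=float) / fs * 1000.0, label=BeatLabel.R_PEAK
    )
    refined = refine_rpeaks(bp, fs, coarse, window_ms=state.refine_window_ms)
    # refinement can nudge neighbours together; re-impose the refractory gap
    kept: list[float] = []
    for t in refined.times:
        if not kept or t - kept[-1] >= state.refractory_ms:
            kept.append(t)
    return BeatSeries(times=np.asarray(kept), label=BeatLabel.R_PEAK)


def refine_rpeaks(
    ecg: np.ndarray, fs: float, coarse: BeatSeries, window_ms: float = 40.0
) -> BeatSeries:
    """Snap each coarse time to the argmax of ``ecg`` within ``+/-window_ms``.

    Order is preserved, boundary windows are clamped to the signal support,
    and times refining to the same sample are collapsed to one.
    """
    ecg = np.asarray(ecg, dtype=float)
    half = max(0, int(round(window_ms / 1000.0 * fs)))
    refined: list[int] = []
    for t in coarse.times:
        center = int(round(t / 1000.0 * fs))
        center = min(max(center, 0), ecg.size - 1)
        lo = max(0, center - half)
        hi = min(ecg.size, center + half + 1)
        idx = lo + int(np.argmax(ecg[lo:hi]))
        if not refined or idx > refined[-1]:
            refined.append(idx)
    return BeatSeries(
        times=np.asarray(refined, dtype=float) / fs * 1000.0, label=coarse.label
    )
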