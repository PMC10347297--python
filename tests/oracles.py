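"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities from first principles (explicit
per-alignment loops, textbook formulas) and stay independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np


def ncc_bruteforce(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Direct per-alignment evaluation of the zero-normalized NCC formula."""
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    m = w.size
    wc = w - w.mean()
    w_ss = float(np.sum(wc * wc))
    out = np.empty(x.size - m + 1)
    for i in range(out.size):
        win = x[i : i + m]
        xc = win - win.mean()
        x_ss = float(np.sum(xc * xc))
        den = np.sqrt(x_ss * w_ss)
        out[i] = 0.0 if x_ss <= 1e-12 * max(1.0, float(np.max(x * x))) else float(
            np.sum(xc * wc)
        ) / den
    return out


def local_maxima(v: np.ndarray) -> list[int]:
    """Strict interior local maxima (plateau: first sample, right edge falls)."""
    idx = []
    i = 1
    n = v.size
    while i < n - 1:
        if v[i - 1] < v[i]:
            j = i
            while j < n - 1 and v[j + 1] == v[j]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                idx.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return idx


def prominence_bruteforce(v: np.ndarray, peak: int) -> float:
    """Topographic prominence by scanning to higher ground on each side."""
    h = v[peak]
    left_min = h
    j = peak - 1
    while j >= 0 and v[j] <= h:
        left_min = min(left_min, v[j])
        j -= 1
    right_min = h
    j = peak + 1
    while j < v.size and v[j] <= h:
        right_min = min(right_min, v[j])
        j += 1
    return float(h - max(left_min, right_min))


def pick_peaks_bruteforce(
    v: np.ndarray, fs: float, min_prominence: float, min_distance_ms: float
) -> list[int]:
    """Prominence filter, then greedy retention by descending height
    (ties: earlier index) under the pairwise minimum-distance constraint."""
    cands = [
        p for p in local_maxima(v) if prominence_bruteforce(v, p) >= min_prominence
    ]
    cands.sort(key=lambda p: (-v[p], p))
    min_gap = min_distance_ms / 1000.0 * fs
    kept: list[int] = []
    for p in cands:
        if all(abs(p - k) >= min_gap for k in kept):
            kept.append(p)
    return sorted(kept)
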