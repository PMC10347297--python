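"""Synthetic paired ECG + GCG recordings with exact ground truth.

The generator emulates the statistical structure the detector assumes:

* a quasi-periodic beat train with Gaussian (truncated) RR variability;
* an ECG with a dominant R spike per beat plus smaller P/T humps;
* a GCG beat built from two Hann-windowed sinusoid bursts — a systolic
  complex (in the 10-25 Hz band the 7-30 Hz filter passes) followed by
  a lower-amplitude diastolic complex — placed a physiological,
  per-beat-jittered R-to-AO delay after each R peak;
* respiratory amplitude modulation, per-beat morphology jitter, and
  additive white Gaussian noise at a prescribed SNR versus the clean
  signal RMS.

Everything is a pure function of (config, seed); ground truth records
R times, AO (systolic-anchor) times, and per-beat complex boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .signal_io import BeatLabel, BeatSeries, Recording, write_beats, write_recording

__all__ = [
    "GroundTruth",
    "SynthConfig",
    "generate_dataset",
    "generate_rr",
    "synth_ecg",
    "synth_gcg",
]

#: Lead-in before the first R peak and tail after the last beat, ms.
_PAD_MS = 1000.0


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters.

    Defaults describe a resting adult: mean RR 800 ms (75 bpm) with
    SDNN 50 ms, an R-to-AO (pre-ejection) delay of 100 +/- 3 ms, a
    systolic complex at 18 Hz lasting 120 ms, a diastolic complex at
    60% amplitude / 14 Hz / 100 ms starting 320 ms after systolic
    onset, respiration at 0.25 Hz modulating amplitude by 20%, 5%
    per-beat morphology jitter, and 10 dB additive-noise SNR.
    """

    n_beats: int = 200
    mean_rr_ms: float = 800.0
    sdnn_ms: float = 50.0
    fs: float = 1000.0
    r_ao_delay_ms: float = 100.0
    r_ao_jitter_ms: float = 3.0
    sys_freq_hz: float = 18.0
    sys_duration_ms: float = 120.0
    dia_freq_hz: float = 14.0
    dia_duration_ms: float = 100.0
    dia_rel_amp: float = 0.6
    dia_offset_ms: float = 320.0  # diastolic onset after systolic onset
    morphology_jitter: float = 0.05
    resp_rate_hz: float = 0.25
    resp_mod_depth: float = 0.2
    snr_db: float | None = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 250:
            raise ValueError("fs must be >= 250 Hz")
        if not 0 < self.dia_rel_amp < 1:
            raise ValueError("dia_rel_amp must lie in (0, 1)")
        for f in (self.sys_freq_hz, self.dia_freq_hz, self.resp_rate_hz):
            if f >= self.fs / 2:
                raise ValueError(f"rate {f} Hz at or above Nyquist")
        beat_span = self.dia_offset_ms + self.dia_duration_ms
        if self.mean_rr_ms <= 2 * (self.sys_duration_ms + self.dia_duration_ms):
            raise ValueError("mean RR too short for the configured complexes")
        if beat_span >= self.mean_rr_ms - 4 * self.sdnn_ms:
            raise ValueError(
                f"beat span {beat_span} ms overlaps the next cycle at the "
                f"shortest admissible RR ({self.mean_rr_ms - 4 * self.sdnn_ms} ms)"
            )


@dataclass
class GroundTruth:
    """Per-beat fiducials (ms): R peak, AO anchor, complex boundaries.

    Invariant per beat: r < systolic_onset <= ao < diastolic_offset.
    """

    r_times_ms: np.ndarray
    ao_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    systolic_onset_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    diastolic_offset_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def r_series(self) -> BeatSeries:
        return BeatSeries(times=self.r_times_ms, label=BeatLabel.R_PEAK)

    def ao_series(self) -> BeatSeries:
        return BeatSeries(times=self.ao_times_ms, label=BeatLabel.GROUND_TRUTH)


def generate_rr(
    n: int, mean_rr_ms: float = 800.0, sdnn_ms: float = 50.0, seed: int = 0
) -> np.ndarray:
    """n RR intervals ~ Normal(mean, sdnn) truncated at mean +/- 4*sdnn."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if mean_rr_ms <= 0 or sdnn_ms < 0:
        raise ValueError("mean_rr_ms must be positive and sdnn_ms non-negative")
    if sdnn_ms > 0 and mean_rr_ms <= 4 * sdnn_ms:
        raise ValueError("need mean_rr_ms > 4*sdnn_ms for truncation safety")
    rng = np.random.default_rng(seed)
    rr = rng.normal(mean_rr_ms, sdnn_ms, size=n)
    return np.clip(rr, mean_rr_ms - 4 * sdnn_ms, mean_rr_ms + 4 * sdnn_ms)


def _r_times_from_rr(rr: np.ndarray, fs: float) -> np.ndarray:
    """R times on the sample grid: first beat one pad after start."""
    raw = _PAD_MS + np.concatenate([[0.0], np.cumsum(rr[:-1])]) if rr.size else np.empty(0)
    return np.round(raw / 1000.0 * fs) / fs * 1000.0


def _gauss_bump(t_ms: np.ndarray, center_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center_ms) / sigma_ms) ** 2)


def _add_noise(clean: np.ndarray, snr_db: float | None, rng) -> np.ndarray:
    if snr_db is None or not np.isfinite(snr_db):
        return clean.copy()
    rms = float(np.sqrt(np.mean(clean**2)))
    if rms == 0:
        return clean.copy()
    sigma = rms * 10 ** (-snr_db / 20.0)
    return clean + rng.normal(0.0, sigma, size=clean.size)


def synth_ecg(
    rr: np.ndarray, fs: float = 1000.0, seed: int = 0, snr_db: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize an ECG for the given RR train.

    Each beat is a dominant Gaussian R spike (sigma 12 ms, amplitude 1)
    flanked by Q/S dips and smaller P and T humps.  Returns the signal
    and the R-peak times (ms, on the sample grid, exact apex samples).
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    rr = np.asarray(rr, dtype=float)
    rng = np.random.default_rng(seed)
    r_times = _r_times_from_rr(rr, fs)
    duration_ms = (r_times[-1] if r_times.size else 0.0) + _PAD_MS
    n = int(round(duration_ms / 1000.0 * fs)) + 1
    t = np.arange(n) / fs * 1000.0
    clean = np.zeros(n)
    for r in r_times:
        clean += 1.0 * _gauss_bump(t, r, 12.0)
        clean -= 0.12 * _gauss_bump(t, r - 35.0, 9.0)
        clean -= 0.15 * _gauss_bump(t, r + 35.0, 9.0)
        clean += 0.15 * _gauss_bump(t, r - 180.0, 25.0)
        clean += 0.30 * _gauss_bump(t, r + 280.0, 60.0)
    return _add_noise(clean, snr_db, rng), r_times


def synth_gcg(
    rr: np.ndarray, cfg: SynthConfig, seed: int | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize the GCG channel and full ground truth for an RR train."""
    cfg.validate()
    rr = np.asarray(rr, dtype=float)
    if rr.size and rr.min() <= cfg.dia_offset_ms + cfg.dia_duration_ms:
        raise ValueError(
            f"RR interval of {rr.min():.0f} ms overlaps the beat span "
            f"({cfg.dia_offset_ms + cfg.dia_duration_ms:.0f} ms)"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.fs
    r_times = _r_times_from_rr(rr, fs)
    duration_ms = (r_times[-1] if r_times.size else 0.0) + _PAD_MS
    n = int(round(duration_ms / 1000.0 * fs)) + 1
    t = np.arange(n) / fs * 1000.0
    clean = np.zeros(n)

    nb = r_times.size
    delays = cfg.r_ao_delay_ms + cfg.r_ao_jitter_ms * rng.standard_normal(nb)
    amp_jit = 1.0 + cfg.morphology_jitter * rng.standard_normal(nb)
    freq_jit = 1.0 + cfg.morphology_jitter * rng.standard_normal(nb)

    ao_times = r_times + delays
    sys_onsets = ao_times - cfg.sys_duration_ms / 2.0
    dia_onsets = sys_onsets + cfg.dia_offset_ms
    dia_offsets = dia_onsets + cfg.dia_duration_ms

    def burst(center_ms: float, dur_ms: float, freq_hz: float, amp: float):
        lo = int(np.floor((center_ms - dur_ms / 2) / 1000.0 * fs))
        hi = int(np.ceil((center_ms + dur_ms / 2) / 1000.0 * fs))
        lo, hi = max(lo, 0), min(hi, n - 1)
        seg = t[lo : hi + 1]
        phase = (seg - center_ms) / 1000.0
        hann = 0.5 * (1 + np.cos(2 * np.pi * phase / (dur_ms / 1000.0)))
        hann[np.abs(phase) > dur_ms / 2000.0] = 0.0
        clean[lo : hi + 1] += amp * hann * np.cos(2 * np.pi * freq_hz * phase)

    for j in range(nb):
        a = max(amp_jit[j], 0.1)
        f_sys = cfg.sys_freq_hz * max(freq_jit[j], 0.5)
        f_dia = cfg.dia_freq_hz * max(freq_jit[j], 0.5)
        burst(ao_times[j], cfg.sys_duration_ms, f_sys, a)
        burst(dia_onsets[j] + cfg.dia_duration_ms / 2.0, cfg.dia_duration_ms,
              f_dia, a * cfg.dia_rel_amp)

    if cfg.resp_mod_depth > 0:
        clean *= 1.0 + cfg.resp_mod_depth * np.sin(
            2 * np.pi * cfg.resp_rate_hz * t / 1000.0
        )
    truth = GroundTruth(
        r_times_ms=r_times,
        ao_times_ms=ao_times,
        systolic_onset_ms=sys_onsets,
        diastolic_offset_ms=dia_offsets,
    )
    return _add_noise(clean, cfg.snr_db, rng), truth


def generate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Paired ECG + GCG recording and ground truth, pure in (cfg, seed)."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rr_seed, ecg_seed, gcg_seed = (int(s) % 2**31 for s in ss.generate_state(3))
    rr = generate_rr(cfg.n_beats, cfg.mean_rr_ms, cfg.sdnn_ms, seed=rr_seed)
    ecg, r_times = synth_ecg(rr, cfg.fs, seed=ecg_seed, snr_db=cfg.snr_db)
    gcg, truth = synth_gcg(rr, cfg, seed=gcg_seed)
    # the two channels are rendered over identical grids by construction
    m = min(ecg.size, gcg.size)
    rec = Recording(channels={"ecg": ecg[:m], "gcgy": gcg[:m]}, fs=cfg.fs,
                    meta={"synthetic": True, "seed": cfg.seed})
    assert np.array_equal(r_times, truth.r_times_ms)
    return rec, truth


def generate_dataset(cfg: SynthConfig, path: str | Path) -> dict[str, Path]:
    """Write rec.csv, truth_r.csv, truth_ao.csv, truth_beats.csv, config.json.

    Outputs are byte-identical across calls with the same (cfg, seed).
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    rec, truth = generate_recording(cfg)
    paths = {
        "recording": out / "rec.csv",
        "truth_r": out / "truth_r.csv",
        "truth_ao": out / "truth_ao.csv",
        "truth_beats": out / "truth_beats.csv",
        "config": out / "config.json",
    }
    write_recording(rec, paths["recording"])
    write_beats(truth.r_series(), paths["truth_r"])
    write_beats(truth.ao_series(), paths["truth_ao"])
    with open(paths["truth_beats"], "w", encoding="utf-8") as fh:
        fh.write("r_ms,ao_ms,systolic_onset_ms,diastolic_offset_ms\n")
        for row in zip(truth.r_times_ms, truth.ao_times_ms,
                       truth.systolic_onset_ms, truth.diastolic_offset_ms):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
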