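"""End-to-end orchestration: ingest -> preprocess -> R peaks -> template ->
NCC detection -> cycle annotation -> agreement statistics.

`run_pipeline` is the library entry point the CLI wraps.  All stage
parameters default to the working values of the method: 1 kHz working
rate, ECG band 0.5-40 Hz + 50 Hz comb notch, GCG band 7-30 Hz, NCC peak
prominence 0.5 with 500 ms minimum spacing, +/-150 ms annotation
tolerance.  Artifacts (rpeaks.csv, beats.csv, annotation.csv, pairs.csv,
report.json) are written deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import beat_annotation, ecg_reference, stats, template_matching
from .preprocessing import DEFAULT_NOTCH_Q, preprocess_ecg, preprocess_gcg
from .signal_io import (
    BeatSeries,
    Recording,
    read_recording,
    resample_linear,
    write_beats,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("gyrobeat")


class PipelineError(RuntimeError):
    """Raised with the failing stage's name when a stage cannot proceed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full run configuration; defaults reproduce the method's parameters."""

    input_path: str | None = None
    ecg_channel: str = "ecg"
    gcg_channel: str = "gcgy"
    input_fs: float | None = None  # declared rate of the CSV input
    target_fs: float = 1000.0
    ecg_band_hz: tuple[float, float] = (0.5, 40.0)
    gcg_band_hz: tuple[float, float] = (7.0, 30.0)
    filter_order: int = 4
    notch_base_hz: float = 50.0
    notch_q: float = DEFAULT_NOTCH_Q
    min_prominence: float = 0.5
    min_distance_ms: float = 500.0
    template_start_ms: float | None = None  # None + None => auto template
    template_end_ms: float | None = None
    delay_tol_ms: float = 150.0
    out_dir: str = "gyrobeat_out"
    log_level: str = "INFO"

    @property
    def auto_template(self) -> bool:
        return self.template_start_ms is None or self.template_end_ms is None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # surface the failing stage by name
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


def run_pipeline(
    cfg: PipelineConfig, recording: Recording | None = None
) -> dict:
    """Run the whole detection + evaluation chain; returns the run report.

    A ``recording`` may be passed directly (e.g. from the synthetic
    generator); otherwise ``cfg.input_path``/``cfg.input_fs`` are used.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("ingest")
    def ingest() -> Recording:
        if recording is not None:
            return recording
        if cfg.input_path is None or cfg.input_fs is None:
            raise ValueError("input_path and input_fs required without a recording")
        return read_recording(
            cfg.input_path, fs=cfg.input_fs,
            channels=[cfg.ecg_channel, cfg.gcg_channel],
        )

    @_stage("resample")
    def resample(rec: Recording) -> Recording:
        return resample_linear(rec, cfg.target_fs)

    @_stage("preprocess")
    def preprocess(rec: Recording) -> tuple[np.ndarray, np.ndarray]:
        ecg = preprocess_ecg(
            rec.channels[cfg.ecg_channel], rec.fs,
            low_hz=cfg.ecg_band_hz[0], high_hz=cfg.ecg_band_hz[1],
            order=cfg.filter_order, notch_base_hz=cfg.notch_base_hz,
            notch_q=cfg.notch_q,
        )
        gcg = preprocess_gcg(
            rec.channels[cfg.gcg_channel], rec.fs,
            low_hz=cfg.gcg_band_hz[0], high_hz=cfg.gcg_band_hz[1],
            order=cfg.filter_order,
        )
        return ecg, gcg

    @_stage("rpeaks")
    def rpeaks(ecg: np.ndarray, fs: float) -> BeatSeries:
        return ecg_reference.pan_tompkins(ecg, fs)

    @_stage("template")
    def template(gcg: np.ndarray, fs: float) -> template_matching.Template:
        if cfg.auto_template:
            return template_matching.suggest_template(gcg, fs)
        rec_f = Recording(channels={cfg.gcg_channel: gcg}, fs=fs)
        return template_matching.select_template(
            rec_f, cfg.gcg_channel, cfg.template_start_ms, cfg.template_end_ms
        )

    @_stage("detect")
    def detect(gcg, fs, tpl) -> BeatSeries:
        series = template_matching.ncc(gcg, tpl)
        params = template_matching.PeakParams(
            min_prominence=cfg.min_prominence, min_distance_ms=cfg.min_distance_ms
        )
        return template_matching.detect_ncc_peaks(
            series, params, anchor_offset=tpl.anchor_offset
        )

    @_stage("annotate")
    def annotate_stage(beats, rp):
        return beat_annotation.annotate(beats, rp, delay_tol_ms=cfg.delay_tol_ms)

    @_stage("evaluate")
    def evaluate(annotations, counts, rp):
        pairs = beat_annotation.pair_valid_ibis(annotations, rp)
        metrics = stats.detection_metrics(counts)
        agreement = stats.agreement_report(pairs) if len(pairs) >= 3 else None
        return pairs, metrics, agreement

    rec = resample(ingest())
    ecg_f, gcg_f = preprocess(rec)
    rp = rpeaks(ecg_f, rec.fs)
    tpl = template(gcg_f, rec.fs)
    beats = detect(gcg_f, rec.fs, tpl)
    annotations, counts = annotate_stage(beats, rp)
    pairs, metrics, agreement = evaluate(annotations, counts, rp)

    write_beats(rp, out / "rpeaks.csv")
    write_beats(beats, out / "beats.csv")
    with open(out / "annotation.csv", "w", encoding="utf-8") as fh:
        fh.write("cycle_start_ms,cycle_end_ms,label,matched_ms,n_peaks,extra_fp\n")
        for a in annotations:
            matched = "" if a.matched_ms is None else repr(float(a.matched_ms))
            fh.write(
                f"{a.window_ms[0]!r},{a.window_ms[1]!r},{a.label.value},"
                f"{matched},{a.peaks_ms.size},{a.extra_fp}\n"
            )
    with open(out / "pairs.csv", "w", encoding="utf-8") as fh:
        fh.write("ref_ibi_ms,test_ibi_ms\n")
        for r, tst in zip(pairs.ref_ibi, pairs.test_ibi):
            fh.write(f"{float(r)!r},{float(tst)!r}\n")

    report = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "template": {
            "start_ms": tpl.start_ms,
            "end_ms": tpl.end_ms,
            "n_samples": int(tpl.samples.size),
            "anchor_offset": tpl.anchor_offset,
        },
        "counts": {"TP": counts.TP, "FP": counts.FP, "FN": counts.FN,
                   "DE": counts.DE, "n_cycles": counts.n_cycles},
        "metrics": {"sensitivity_pct": metrics.sensitivity_pct,
                    "ppv_pct": metrics.ppv_pct},
        "agreement": agreement.to_dict() if agreement is not None else None,
        "artifacts": {name: str(out / f"{name}.csv")
                      for name in ("rpeaks", "beats", "annotation", "pairs")},
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
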