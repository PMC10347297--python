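# gyrobeat

ECG-free heartbeat detection in **gyrocardiography (GCG)** signals by
normalized cross-correlation (NCC) template matching, together with the
ECG-referenced evaluation protocol used to validate such detectors.

GCG records the angular velocity of the chest wall induced by the
twisting/untwisting motion of the heart, measured with a MEMS gyroscope;
the component about the cranio–caudal axis (GCGy) carries most of the
cardiac signal. Each heartbeat appears as two oscillatory bursts — a
**systolic** and a **diastolic complex** — whose energy lies roughly in the
7–30 Hz band. The package is aimed at researchers in cardio-mechanical
monitoring who need (a) a reproducible beat detector that does not require a
concurrent ECG at run time, and (b) the statistical machinery to benchmark
it against an ECG reference.

## Method

1. **Preprocessing** — signals are linearly interpolated to a 1 kHz working
   rate; the ECG is band-passed 0.5–40 Hz (4th-order zero-phase Butterworth)
   with a 50 Hz comb notch; the GCG channel is band-passed 7–30 Hz.
2. **Reference R peaks** — Pan–Tompkins detection on the preprocessed ECG
   (5–15 Hz QRS enhancement, derivative, squaring, 150 ms moving-window
   integration, dual adaptive thresholds with search-back).
3. **Template selection** — a single heartbeat template spanning both
   complexes is carved from the band-passed GCG, either manually (sample
   interval) or by a heuristic that starts the template two–three waves
   before the highest systolic peak and ends it one zero crossing after the
   last diastolic excursion.
4. **Detection** — the zero-normalized cross-correlation

   $$\mathrm{NCC}(i)=\frac{\sum_k (x_{i+k}-\bar x_i)(w_k-\bar w)}
   {\sqrt{\sum_k (x_{i+k}-\bar x_i)^2\;\sum_k (w_k-\bar w)^2}}\in[-1,1]$$

   is computed for every alignment of template $w$ against signal window
   $x_i$; beats are the NCC local maxima with topographic prominence ≥ 0.5
   and pairwise spacing ≥ 500 ms, reported at the template's systolic
   anchor.
5. **Evaluation** — reference R–R cycles are annotated as TP / FP / FN / DE
   (a *detection error* is a cycle whose only detection is temporally
   implausible; it enters both metric denominators):

   $$\mathrm{Sensitivity}=\frac{TP}{TP+FN+DE}\cdot 100,\qquad
     \mathrm{PPV}=\frac{TP}{TP+FP+DE}\cdot 100$$

   Inter-beat intervals from consecutive R peaks and NCC peaks (pairs not
   corrupted by FN/DE) are compared by OLS regression, Pearson correlation
   and Bland–Altman analysis (bias ± 1.96·SD limits of agreement with
   t-based 95% CIs).

A synthetic paired ECG+GCG generator (`gyrobeat.synthetic`) provides
ground-truth recordings with configurable RR variability, R-to-AO delay
jitter, morphology jitter, respiratory amplitude modulation and SNR, so the
whole pipeline is testable without any external database.

## Worked example

```python
from gyrobeat import (SynthConfig, generate_recording, preprocess_ecg,
                      preprocess_gcg, pan_tompkins, suggest_template,
                      detect_heartbeats, annotate, pair_valid_ibis,
                      detection_metrics, agreement_report)

rec, truth = generate_recording(SynthConfig(n_beats=120, seed=7))  # 10 dB SNR
rpeaks = pan_tompkins(preprocess_ecg(rec.channels["ecg"], rec.fs), rec.fs)
gcg = preprocess_gcg(rec.channels["gcgy"], rec.fs)
beats = detect_heartbeats(rec.channels["gcgy"], rec.fs,
                          suggest_template(gcg, rec.fs))
ann, counts = annotate(beats, rpeaks)
m = detection_metrics(counts)
rep = agreement_report(pair_valid_ibis(ann, rpeaks))
print(f"TP={counts.TP} FP={counts.FP} FN={counts.FN} DE={counts.DE}")
print(f"sensitivity={m.sensitivity_pct:.1f}%  PPV={m.ppv_pct:.1f}%")
print(f"slope={rep.slope:.3f}  bias={rep.bias_ms:.3f} ms  "
      f"LoA=[{rep.loa_low_ms:.2f}, {rep.loa_high_ms:.2f}] ms")
```

prints

```
TP=119 FP=0 FN=0 DE=0
sensitivity=100.0%  PPV=100.0%
slope=0.990  bias=-0.008 ms  LoA=[-9.78, 9.77] ms
```

i.e. every one of the 119 evaluated cardiac cycles contains exactly one
plausible detection, the GCG-derived inter-beat intervals track the ECG
reference with near-unit slope, and 95% of interval differences lie within
about ±10 ms — the scale set by the ±3 ms beat-to-beat jitter of the
R-to-AO (pre-ejection) delay, which no ECG-free mechanical detector can
remove.

The same flow is available from the shell:

```bash
gyrobeat synth --seed 7 --n-beats 120 --out ds/
gyrobeat run --input ds/rec.csv --fs 1000 --out out/
```

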