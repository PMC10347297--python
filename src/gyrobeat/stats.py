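"""Detection metrics and inter-beat-interval agreement statistics.

Sensitivity and positive predictive value follow the detection-error
convention in which a DE cycle (single implausible detection, no true
beat) enters both denominators:

    sensitivity = 100 * TP / (TP + FN + DE)
    PPV         = 100 * TP / (TP + FP + DE)

Agreement between reference (ECG) and test (GCG) intervals is assessed
by OLS regression of test on reference, Pearson correlation, and
Bland-Altman analysis in its classic form: bias = mean difference,
limits of agreement = bias +/- 1.96 * SD, with t-based 95% confidence
intervals (SE of each LoA = SD * sqrt(3/n)).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sst

from .beat_annotation import DetectionCounts, IBIPairs

__all__ = [
    "AgreementReport",
    "MetricResult",
    "agreement_report",
    "bland_altman",
    "detection_metrics",
    "pearson",
    "ppv",
    "regress",
    "sensitivity",
]


@dataclass(frozen=True)
class MetricResult:
    sensitivity_pct: float
    ppv_pct: float

    def rounded(self) -> tuple[int, int]:
        """Nearest-integer percentages, the reporting convention used here."""
        return round(self.sensitivity_pct), round(self.ppv_pct)


@dataclass(frozen=True)
class AgreementReport:
    slope: float
    intercept_ms: float
    r_squared: float
    pearson_r: float
    pearson_p: float
    bias_ms: float
    bias_p: float
    loa_low_ms: float
    loa_high_ms: float
    ci_bias_ms: tuple[float, float]
    ci_loa_low_ms: tuple[float, float]
    ci_loa_high_ms: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("ci_bias_ms", "ci_loa_low_ms", "ci_loa_high_ms"):
            d[key] = list(d[key])
        return d


def sensitivity(counts: DetectionCounts) -> float:
    """100 * TP / (TP + FN + DE)."""
    denom = counts.TP + counts.FN + counts.DE
    if denom == 0:
        raise ValueError("sensitivity undefined: no evaluated cycles")
    return 100.0 * counts.TP / denom


def ppv(counts: DetectionCounts) -> float:
    """100 * TP / (TP + FP + DE)."""
    denom = counts.TP + counts.FP + counts.DE
    if denom == 0:
        raise ValueError("PPV undefined: no detections")
    return 100.0 * counts.TP / denom


def detection_metrics(counts: DetectionCounts) -> MetricResult:
    return MetricResult(sensitivity_pct=sensitivity(counts), ppv_pct=ppv(counts))


def _paired(ref, test, min_n: int):
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape or ref.ndim != 1:
        raise ValueError("ref and test must be 1-D arrays of equal length")
    if ref.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {ref.size}")
    return ref, test


def regress(ref, test) -> tuple[float, float, float]:
    """OLS of test on ref: returns (slope, intercept, R^2)."""
    ref, test = _paired(ref, test, 3)
    if np.ptp(ref) == 0:
        raise ValueError("reference intervals are constant; regression undefined")
    res = sst.linregress(ref, test)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def pearson(ref, test) -> tuple[float, float]:
    """Sample Pearson r with two-sided t-test p-value."""
    ref, test = _paired(ref, test, 3)
    if np.ptp(ref) == 0 or np.ptp(test) == 0:
        raise ValueError("constant input; correlation undefined")
    res = sst.pearsonr(ref, test)
    return float(res.statistic), float(res.pvalue)


def bland_altman(ref, test) -> dict:
    """Bias, 1.96-SD limits of agreement, and their 95% CIs.

    CI of the bias: bias +/- t_{0.975,n-1} * sd/sqrt(n); CI of each LoA
    uses SE = sd * sqrt(3/n) with the same t quantile.  ``bias_p`` is a
    one-sample t-test of zero mean difference.
    """
    ref, test = _paired(ref, test, 3)
    d = test - ref
    n = d.size
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tq = float(sst.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    if sd > 0:
        bias_p = float(sst.ttest_1samp(d, 0.0).pvalue)
    else:
        bias_p = 0.0 if bias != 0 else 1.0
    return {
        "bias_ms": bias,
        "bias_p": bias_p,
        "loa_low_ms": loa_low,
        "loa_high_ms": loa_high,
        "ci_bias_ms": (bias - tq * se_bias, bias + tq * se_bias),
        "ci_loa_low_ms": (loa_low - tq * se_loa, loa_low + tq * se_loa),
        "ci_loa_high_ms": (loa_high - tq * se_loa, loa_high + tq * se_loa),
        "n": n,
    }


def agreement_report(pairs: IBIPairs) -> AgreementReport:
    """Full regression + correlation + Bland-Altman report on paired IBIs."""
    ref, test = pairs.ref_ibi, pairs.test_ibi
    slope, intercept, r2 = regress(ref, test)
    r, p = pearson(ref, test)
    ba = bland_altman(ref, test)
    return AgreementReport(
        slope=slope,
        intercept_ms=intercept,
        r_squared=r2,
        pearson_r=r,
        pearson_p=p,
        **ba,
    )
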