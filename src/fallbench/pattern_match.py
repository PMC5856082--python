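"""Correlation of 5 s activity patterns with signal segments, refined by gyroscope.

A fall pattern (per-axis acceleration templates plus z/y gyroscope
templates) is the pointwise mean of 5 s excerpts centred on the SMV
peak of training fall recordings. Detection slides a 5 s segment over a
recording: the acceleration matches when the mean of the three per-axis
Pearson correlations exceeds TH_CA; the gyroscope then confirms via the
z-axis template when |Gz| is meaningful (exceeds TH_G), falling back to
the y-axis, with the template correlation compared against TH_CG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, FallbenchError
from .signals import ImuRecording, magnitude

log = logging.getLogger(__name__)

PATTERN_DURATION_S = 5.0
DEFAULT_STRIDE_S = 0.25


@dataclass(frozen=True)
class PatternThresholds:
    th_ca: float   # acceleration correlation, in (0, 1)
    th_g: float    # rad/s; gyro significance gate, shared by z and y
    th_cg: float   # gyro correlation, in (0, 1); shared by z and y


@dataclass
class ActivityPattern:
    """Mean 5 s templates of one activity class."""

    fs: float
    acc_template: np.ndarray      # (n, 3)
    gyro_z_template: np.ndarray   # (n,)
    gyro_y_template: np.ndarray   # (n,)
    label: str = "fall"
    duration_s: float = PATTERN_DURATION_S

    def __post_init__(self) -> None:
        n = int(round(self.duration_s * self.fs))
        if self.acc_template.shape != (n, 3):
            raise ContractError(
                f"acc_template must be ({n}, 3), got {self.acc_template.shape}"
            )
        if self.gyro_z_template.shape != (n,) or self.gyro_y_template.shape != (n,):
            raise ContractError(f"gyro templates must be ({n},)")

    def __len__(self) -> int:
        return self.acc_template.shape[0]


def build_pattern(
    recordings: list[ImuRecording],
    duration_s: float = PATTERN_DURATION_S,
    label: str = "fall",
) -> ActivityPattern:
    """Average duration_s excerpts of one class, aligned on the SMV peak.

    Recordings whose centred excerpt does not fit are excluded with a
    warning; if all are excluded this raises.
    """
    if not recordings:
        raise ContractError("build_pattern needs at least one recording")
    fs = recordings[0].fs
    n = int(round(duration_s * fs))
    half = n // 2
    acc, gz, gy = [], [], []
    for rec in recordings:
        if rec.fs != fs:
            raise ContractError("all recordings must share one sampling rate")
        peak = int(np.argmax(magnitude(rec.A)))
        start = peak - half
        if start < 0 or start + n > len(rec):
            log.warning(
                "recording %s excluded from pattern: excerpt out of range", rec.label
            )
            continue
        acc.append(rec.A[start: start + n])
        gz.append(rec.G[start: start + n, 2])
        gy.append(rec.G[start: start + n, 1])
    if not acc:
        raise FallbenchError("no recording long enough to contribute to the pattern")
    return ActivityPattern(
        fs=fs,
        acc_template=np.mean(acc, axis=0),
        gyro_z_template=np.mean(gz, axis=0),
        gyro_y_template=np.mean(gy, axis=0),
        label=label,
        duration_s=duration_s,
    )


def correlate(segment: np.ndarray, template: np.ndarray) -> float:
    """Pearson correlation in [-1, 1]; zero-variance inputs yield 0."""
    x = np.asarray(segment, dtype=float)
    y = np.asarray(template, dtype=float)
    if x.shape != y.shape:
        raise ContractError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ContractError("correlation needs at least two samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.clip(xd @ yd / (sx * sy), -1.0, 1.0))


def segment_scores(
    rec: ImuRecording, pattern: ActivityPattern, stride_s: float = DEFAULT_STRIDE_S
) -> list[dict]:
    """Per-segment correlation scores and gyro magnitudes (threshold-free)."""
    if pattern.fs != rec.fs:
        raise ContractError("pattern and recording sampling rates differ")
    n, L = len(rec), len(pattern)
    stride = max(1, int(round(stride_s * rec.fs)))
    out = []
    for start in range(0, n - L + 1, stride):
        seg_a = rec.A[start: start + L]
        seg_gz = rec.G[start: start + L, 2]
        seg_gy = rec.G[start: start + L, 1]
        acc_corr = float(
            np.mean([correlate(seg_a[:, i], pattern.acc_template[:, i]) for i in range(3)])
        )
        out.append(
            {
                "t_center": (start + L / 2) / rec.fs,
                "acc_corr": acc_corr,
                "gz_max": float(np.max(np.abs(seg_gz))),
                "gy_max": float(np.max(np.abs(seg_gy))),
                "gz_corr": correlate(seg_gz, pattern.gyro_z_template),
                "gy_corr": correlate(seg_gy, pattern.gyro_y_template),
            }
        )
    return out


def detect_from_scores(scores: list[dict], th: PatternThresholds) -> list[float]:
    times = []
    for s in scores:
        if s["acc_corr"] <= th.th_ca:
            continue
        if s["gz_max"] > th.th_g:
            ok = s["gz_corr"] > th.th_cg
        elif s["gy_max"] > th.th_g:
            ok = s["gy_corr"] > th.th_cg
        else:
            ok = False
        if ok:
            times.append(s["t_center"])
    merged: list[float] = []
    for t in sorted(times):
        if not merged or t >= merged[-1] + 1.0:
            merged.append(t)
    return merged


def detect_pattern_match(
    rec: ImuRecording,
    pattern: ActivityPattern,
    th: PatternThresholds,
    stride_s: float = DEFAULT_STRIDE_S,
) -> list[float]:
    """Detection times (s, segment centres); 1 s refractory merging."""
    return detect_from_scores(segment_scores(rec, pattern, stride_s), th)
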