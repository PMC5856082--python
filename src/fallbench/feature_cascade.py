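"""Five-feature sliding-window fall detector on fused accelerometer + gyroscope data.

A 2 s window slides over low-pass-filtered channels. When the L1
acceleration magnitude (SV) exceeds its threshold, four more features
are computed from sub-windows anchored at the SV peak time t_sv:

* AV    - maximum angle between successive acceleration vectors, degrees,
          over (t_sv - 1 s, t_sv + 1 s);
* CA    - angle between the mean acceleration vectors of
          (t_sv - 2 s, t_sv + 1 s) and (t_sv + 1 s, t_sv + 2 s), degrees;
* SV_G  - maximum L1 angular velocity over (t_sv - 1 s, t_sv + 1 s), rad/s;
* SV_GA - maximum L1 angular acceleration (forward differences) over the
          same sub-window, rad/s^2.

A fall is detected when all five exceed their thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigError, ContractError, UndefinedAngleError
from .signals import ImuRecording, sliding_windows

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_WINDOW_S = 2.0
DEFAULT_STRIDE_S = 0.5


@dataclass(frozen=True)
class CascadeThresholds:
    sv: float       # g
    av: float       # degrees
    ca: float       # degrees
    sv_g: float     # rad/s
    sv_ga: float    # rad/s^2


@dataclass
class CascadeFeatures:
    """Feature values for one 2 s window, anchored at the SV peak."""

    sv_max: float
    t_sv: float
    av_angle: float
    ca: float
    sv_g: float
    sv_ga: float


@dataclass
class CascadeCounter:
    """Instrumentation: how often each stage of the cascade ran."""

    windows: int = 0
    secondary_evals: int = 0


def lowpass(x: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass with unit DC gain; length preserved."""
    if not 0 < cutoff < fs / 2:
        raise ConfigError(f"cutoff must lie in (0, fs/2)=(0, {fs / 2}), got {cutoff}")
    b, a = butter(order, cutoff / (fs / 2))
    return filtfilt(b, a, np.asarray(x, dtype=float), axis=0)


def sum_abs(v: np.ndarray) -> np.ndarray:
    """L1 norm along the last axis."""
    return np.abs(np.asarray(v, dtype=float)).sum(axis=-1)


def angle_variation(A_window: np.ndarray) -> float:
    """Maximum successive-sample angle within the window, in degrees."""
    A_window = np.asarray(A_window, dtype=float)
    if A_window.shape[0] < 2:
        raise ContractError("angle_variation needs at least two samples")
    norms = np.linalg.norm(A_window, axis=1)
    if np.any(norms == 0.0):
        raise UndefinedAngleError("zero-norm acceleration vector in window")
    dots = np.einsum("ij,ij->i", A_window[:-1], A_window[1:])
    cosang = np.clip(dots / (norms[:-1] * norms[1:]), -1.0, 1.0)
    return float(np.degrees(np.max(np.arccos(cosang))))


def orientation_change(A_before: np.ndarray, A_after: np.ndarray) -> float:
    """Angle between the mean acceleration vectors of two windows, degrees."""
    A_before = np.asarray(A_before, dtype=float)
    A_after = np.asarray(A_after, dtype=float)
    if A_before.shape[0] == 0 or A_after.shape[0] == 0:
        raise ContractError("both windows must be nonempty")
    mb, me = A_before.mean(axis=0), A_after.mean(axis=0)
    nb, ne = np.linalg.norm(mb), np.linalg.norm(me)
    if nb == 0.0 or ne == 0.0:
        raise UndefinedAngleError("zero mean acceleration vector")
    return float(np.degrees(np.arccos(np.clip(mb @ me / (nb * ne), -1.0, 1.0))))


def angular_acceleration(G_window: np.ndarray, dt: float) -> np.ndarray:
    """Forward differences (G[n+1] - G[n]) / dt; length N-1."""
    G_window = np.asarray(G_window, dtype=float)
    if G_window.shape[0] < 2:
        raise ContractError("angular_acceleration needs at least two samples")
    return np.diff(G_window, axis=0) / dt


def _clip_range(lo: int, hi: int, n: int) -> tuple[int, int]:
    return max(0, lo), min(n, hi)


def window_features(
    A: np.ndarray, G: np.ndarray, fs: float, start: int, end: int
) -> CascadeFeatures | None:
    """Features for the window [start, end) of filtered channels.

    Returns None when the CA after-window would extend past the end of
    the recording (such windows are skipped rather than padded).
    """
    n = A.shape[0]
    sv = sum_abs(A[start:end])
    k = int(np.argmax(sv))
    t_idx = start + k
    one, two = int(round(fs)), int(round(2 * fs))
    if t_idx + two > n:
        return None
    lo, hi = _clip_range(t_idx - one, t_idx + one, n)
    av = angle_variation(A[lo:hi])
    sv_g = float(np.max(sum_abs(G[lo:hi])))
    ga = angular_acceleration(G[lo:hi], 1.0 / fs)
    sv_ga = float(np.max(sum_abs(ga)))
    blo, bhi = _clip_range(t_idx - two, t_idx + one, n)
    ca = orientation_change(A[blo:bhi], A[t_idx + one: t_idx + two])
    return CascadeFeatures(
        sv_max=float(sv[k]),
        t_sv=t_idx / fs,
        av_angle=av,
        ca=ca,
        sv_g=sv_g,
        sv_ga=sv_ga,
    )


def _merge_refractory(times: list[float], refractory_s: float = 1.0) -> list[float]:
    out: list[float] = []
    for t in times:
        if not out or t >= out[-1] + refractory_s:
            out.append(t)
    return out


def filtered_channels(
    rec: ImuRecording, cutoff_hz: float = DEFAULT_CUTOFF_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass filtered acceleration and angular velocity."""
    return lowpass(rec.A, rec.fs, cutoff_hz), lowpass(rec.G, rec.fs, cutoff_hz)


def detect_feature_cascade(
    rec: ImuRecording,
    th: CascadeThresholds,
    window_s: float = DEFAULT_WINDOW_S,
    stride_s: float = DEFAULT_STRIDE_S,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    counter: CascadeCounter | None = None,
) -> list[float]:
    """Detection times (s): windows where all five features exceed their thresholds.

    The SV gate short-circuits the cascade: secondary features are only
    evaluated when the window's SV maximum exceeds ``th.sv``
    (observable through ``counter.secondary_evals``). Detections within
    1 s of an earlier one are merged.
    """
    A, G = filtered_channels(rec, cutoff_hz)
    fs = rec.fs
    times: list[float] = []
    for win in sliding_windows(len(rec), window_s, stride_s, fs):
        if counter is not None:
            counter.windows += 1
        sv = sum_abs(A[win.start:win.end])
        k = int(np.argmax(sv))
        if sv[k] <= th.sv:
            continue
        if counter is not None:
            counter.secondary_evals += 1
        feats = window_features(A, G, fs, win.start, win.end)
        if feats is None:
            log.debug("cascade window at %d skipped: CA after-window out of range", win.start)
            continue
        if (
            feats.av_angle > th.av
            and feats.ca > th.ca
            and feats.sv_g > th.sv_g
            and feats.sv_ga > th.sv_ga
        ):
            times.append(feats.t_sv)
    return _merge_refractory(sorted(times))


def all_window_features(
    rec: ImuRecording,
    window_s: float = DEFAULT_WINDOW_S,
    stride_s: float = DEFAULT_STRIDE_S,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> list[CascadeFeatures]:
    """Features of every window, threshold-independent (used by the search)."""
    A, G = filtered_channels(rec, cutoff_hz)
    out = []
    for win in sliding_windows(len(rec), window_s, stride_s, rec.fs):
        feats = window_features(A, G, rec.fs, win.start, win.end)
        if feats is not None:
            out.append(feats)
    return out


def detect_from_features(
    feats: list[CascadeFeatures], th: CascadeThresholds
) -> list[float]:
    """Thresholding of precomputed window features; same rule as the cascade."""
    times = [
        f.t_sv
        for f in feats
        if f.sv_max > th.sv
        and f.av_angle > th.av
        and f.ca > th.ca
        and f.sv_g > th.sv_g
        and f.sv_ga > th.sv_ga
    ]
    return _merge_refractory(sorted(times))
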