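"""Two-phase (free-fall + impact) fall detector on SMV and vertical acceleration.

Orientation (roll theta_z, pitch theta_y) is tracked by a complementary
filter blending gyroscope integration with accelerometer tilt; the
absolute vertical acceleration projects the acceleration vector onto the
estimated gravity axis. A fall is declared only when both the SMV and
the vertical-acceleration channel show a free-fall swing followed by an
impact swing within one second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ContractError, UndefinedOrientationError
from .signals import ImuRecording


def _wrap(angle):
    """Wrap to (-pi, pi]."""
    a = np.mod(-np.asarray(angle) + np.pi, 2.0 * np.pi)
    return -(a - np.pi)


@dataclass(frozen=True)
class OrientationState:
    """Roll/pitch angle pair in radians, each wrapped to (-pi, pi]."""

    theta_z: float
    theta_y: float


@dataclass(frozen=True)
class ComplementaryFilterConfig:
    alpha: float = 0.95
    dt: float = 1.0 / 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ContractError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.dt <= 0:
            raise ContractError(f"dt must be positive, got {self.dt}")


@dataclass(frozen=True)
class TwoPhaseThresholds:
    """Free-fall / impact swing thresholds, in g, for both channels."""

    smv_ff: float
    smv_ip: float
    av_ff: float
    av_ip: float
    freefall_window_s: float = 0.1
    impact_window_s: float = 1.0


def accel_angles(a: np.ndarray) -> tuple[float, float]:
    """Tilt angles implied by a single acceleration vector.

    Returns ``(theta_az, theta_ay)`` with
    ``theta_az = atan2(Ax, sqrt(Ay^2 + Az^2))`` and
    ``theta_ay = atan2(-Ay, sqrt(Ax^2 + Az^2))``.
    """
    ax, ay, az = (float(v) for v in a)
    if ax == 0.0 and ay == 0.0 and az == 0.0:
        raise UndefinedOrientationError("orientation undefined for a zero acceleration vector")
    theta_az = np.arctan2(ax, np.hypot(ay, az))
    theta_ay = np.arctan2(-ay, np.hypot(ax, az))
    return float(_wrap(theta_az)), float(_wrap(theta_ay))


def complementary_update(
    state: OrientationState,
    a: np.ndarray,
    g: np.ndarray,
    cfg: ComplementaryFilterConfig,
) -> OrientationState:
    """One complementary-filter step:
    ``theta' = alpha * (theta + G dt) + (1 - alpha) * theta_accel``.

    With ``alpha == 1`` the accelerometer is never consulted, so a zero
    acceleration vector is only an error when ``alpha < 1``.
    """
    alpha, dt = cfg.alpha, cfg.dt
    if alpha < 1.0:
        theta_az, theta_ay = accel_angles(a)
    else:
        theta_az = theta_ay = 0.0
    gz, gy = float(g[2]), float(g[1])
    theta_z = alpha * (state.theta_z + gz * dt) + (1.0 - alpha) * theta_az
    theta_y = alpha * (state.theta_y + gy * dt) + (1.0 - alpha) * theta_ay
    return OrientationState(float(_wrap(theta_z)), float(_wrap(theta_y)))


def vertical_acceleration(a: np.ndarray, state: OrientationState) -> float:
    """|Ax sin(theta_z) + Ay sin(theta_y) - Az cos(theta_y) cos(theta_z)| in g."""
    ax, ay, az = (float(v) for v in a)
    return abs(
        ax * np.sin(state.theta_z)
        + ay * np.sin(state.theta_y)
        - az * np.cos(state.theta_y) * np.cos(state.theta_z)
    )


def orientation_series(
    rec: ImuRecording, cfg: ComplementaryFilterConfig | None = None
) -> np.ndarray:
    """Per-sample (theta_z, theta_y) track, initialised from the first sample's tilt.

    The recurrence theta[n] = alpha*(theta[n-1] + G[n] dt) + (1-alpha)*theta_a[n]
    is a first-order IIR filter, evaluated with ``lfilter``; wrapping is
    applied to the result (the tracked tilt never accumulates multiple
    turns in this problem domain).
    """
    if cfg is None:
        cfg = ComplementaryFilterConfig(dt=1.0 / rec.fs)
    alpha, dt = cfg.alpha, cfg.dt
    A, G = rec.A, rec.G
    if alpha < 1.0:
        norms_yz = np.hypot(A[:, 1], A[:, 2])
        norms_xz = np.hypot(A[:, 0], A[:, 2])
        theta_az = np.arctan2(A[:, 0], norms_yz)
        theta_ay = np.arctan2(-A[:, 1], norms_xz)
        if np.any((A == 0.0).all(axis=1)):
            raise UndefinedOrientationError("zero acceleration vector with alpha < 1")
    else:
        theta_az = theta_ay = np.zeros(len(rec))
    theta0_z, theta0_y = accel_angles(A[0])
    out = np.empty((len(rec), 2))
    for col, (theta0, g_idx, th_a) in enumerate(
        [(theta0_z, 2, theta_az), (theta0_y, 1, theta_ay)]
    ):
        x = alpha * G[:, g_idx] * dt + (1.0 - alpha) * th_a
        x[0] = theta0  # state at n=0 is the first-sample tilt, by convention
        y, _ = lfilter([1.0], [1.0, -alpha], x, zi=np.array([0.0]))
        out[:, col] = y
    return _wrap(out)


def vertical_series(
    rec: ImuRecording, cfg: ComplementaryFilterConfig | None = None
) -> np.ndarray:
    """Per-sample absolute vertical acceleration under the tracked orientation."""
    theta = orientation_series(rec, cfg)
    return np.abs(
        rec.A[:, 0] * np.sin(theta[:, 0])
        + rec.A[:, 1] * np.sin(theta[:, 1])
        - rec.A[:, 2] * np.cos(theta[:, 1]) * np.cos(theta[:, 0])
    )


def _rolling_swing(x: np.ndarray, width: int) -> np.ndarray:
    """max - min over every width-sample window, indexed by window start."""
    if width <= 1:
        return np.zeros(len(x))
    v = sliding_window_view(x, width)
    return v.max(axis=1) - v.min(axis=1)


def detect_two_phase(
    smv: np.ndarray,
    av: np.ndarray,
    fs: float,
    th: TwoPhaseThresholds,
) -> list[float]:
    """Detection times (s) from the dual-channel two-phase rule.

    A detection requires, per channel, a 0.1 s window whose max-min
    swing exceeds the free-fall threshold followed within 1 s by a 0.1 s
    window exceeding the impact threshold; the vertical-acceleration
    free-fall window must start within 1 s of the SMV one. Detections
    closer than 1 s are merged, keeping the earliest.
    """
    smv = np.asarray(smv, dtype=float)
    av = np.asarray(av, dtype=float)
    if smv.shape != av.shape:
        raise ContractError("smv and av must have identical length")
    w = max(2, int(round(th.freefall_window_s * fs)))
    horizon = max(1, int(round(th.impact_window_s * fs)))
    if len(smv) < w:
        return []

    d_smv = _rolling_swing(smv, w)
    d_av = _rolling_swing(av, w)
    ff_s = np.flatnonzero(d_smv > th.smv_ff)
    ip_s = d_smv > th.smv_ip
    ff_a = np.flatnonzero(d_av > th.av_ff)
    ip_a = d_av > th.av_ip

    detections: list[float] = []
    refractory_until = -np.inf
    for i in ff_s:
        t_ff = i / fs
        if t_ff < refractory_until - th.impact_window_s:
            continue
        # SMV impact window within (i, i + horizon]
        j_rel = np.flatnonzero(ip_s[i + 1: i + horizon + 1])
        if j_rel.size == 0:
            continue
        # AV free-fall start within 1 s of the SMV free-fall start
        near = ff_a[(ff_a >= i - horizon) & (ff_a <= i + horizon)]
        ok_av = False
        for i2 in near:
            if np.any(ip_a[i2 + 1: i2 + horizon + 1]):
                ok_av = True
                break
        if not ok_av:
            continue
        j = i + 1 + j_rel[0]
        peak = j + int(np.argmax(smv[j: j + w]))
        t_det = peak / fs
        if t_det >= refractory_until:
            detections.append(t_det)
            refractory_until = t_det + th.impact_window_s
    return detections


def detect(
    rec: ImuRecording,
    th: TwoPhaseThresholds,
    cfg: ComplementaryFilterConfig | None = None,
) -> list[float]:
    """Run the full detector on a preprocessed recording."""
    return detect_two_phase(rec.smv(), vertical_series(rec, cfg), rec.fs, th)
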