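"""Seeded generator of fall and ADL IMU recordings.

Falls follow the canonical accelerometer fall waveform: ~1 g pre-fall,
a free-fall dip, a sharp impact spike with a brief rotational tumble,
then post-impact inactivity with a net orientation change. The gravity
direction rotates in a single body plane, and the gyroscope channel is
the exact forward difference of the scripted rotation angle, so
integrating the generated gyroscope recovers the angle implied by the
gravity direction sample-for-sample (zero-noise case).

ADL classes cover periodic locomotion (walking/jogging), jumping
(repeated spikes, no inactivity), sit-down transients, lying (slow
orientation change without a spike), and quiet standing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .signals import ImuRecording, write_recording

ADL_KINDS = ("walking", "jogging", "jumping", "sitting", "lying", "standing")

DEFAULT_ADL_MIX = {
    "walking": 0.25,
    "jogging": 0.15,
    "jumping": 0.15,
    "sitting": 0.15,
    "lying": 0.15,
    "standing": 0.15,
}


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bump(u: np.ndarray) -> np.ndarray:
    """Smooth unit bump supported on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return np.sin(np.pi * u) ** 2


@dataclass(frozen=True)
class FallScenario:
    """Script for one fall recording."""

    pre_fall_s: float = 4.0
    freefall_depth_g: float = 0.4
    freefall_dur_s: float = 0.35
    impact_peak_g: float = 3.0
    impact_rise_s: float = 0.08
    impact_dur_s: float = 0.25
    inactivity_s: float = 4.0
    orientation_change_deg: float = 90.0
    gyro_burst_rads: float = 3.0
    # rotational tumble at impact: what drives the successive-sample
    # angle swing and the angular-acceleration burst
    tumble_amp_rad: float = 1.8
    tumble_freq_hz: float = 4.0
    tumble_tau_s: float = 0.45
    axis: str = "z"            # body axis whose gyro channel carries the rotation
    noise_sd_g: float = 0.02
    gyro_noise_rads: float = 0.01
    gyro_drift_rads: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.impact_peak_g <= 1.0:
            raise ConfigError("impact_peak_g must exceed 1 g")
        if not 0.0 < self.freefall_depth_g < 1.0:
            raise ConfigError("freefall_depth_g must lie in (0, 1) g")
        for name in ("pre_fall_s", "freefall_dur_s", "impact_rise_s", "impact_dur_s", "inactivity_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.axis not in ("z", "y"):
            raise ConfigError("axis must be 'z' or 'y'")


@dataclass(frozen=True)
class FallTruth:
    """Ground-truth annotation emitted alongside a generated fall."""

    impact_time_s: float
    orientation_change_deg: float
    phi: np.ndarray            # scripted rotation angle per sample, rad
    axis: str


@dataclass(frozen=True)
class AdlScenario:
    """Script for one ADL recording; None fields take kind-specific defaults."""

    kind: str = "walking"
    duration_s: float = 12.0
    amplitude_g: float | None = None
    freq_hz: float | None = None
    peak_g: float | None = None          # jumping spike height
    period_s: float | None = None        # jumping spike spacing
    orientation_change_deg: float | None = None   # sitting/lying
    transition_s: float | None = None
    noise_sd_g: float = 0.02
    gyro_noise_rads: float = 0.01
    gyro_drift_rads: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ADL_KINDS:
            raise ConfigError(f"unknown ADL kind {self.kind!r}; choose from {ADL_KINDS}")
        if self.duration_s < 2.0:
            raise ConfigError("duration_s must be at least 2 s")


@dataclass(frozen=True)
class DatasetSpec:
    """Desk-scale corpus: counts, class mix, sampling rate, master seed."""

    n_falls: int = 100
    n_adls: int = 100
    fs: float = 50.0
    seed: int = 0
    adl_mix: dict = field(default_factory=lambda: dict(DEFAULT_ADL_MIX))

    def __post_init__(self) -> None:
        if self.n_falls < 0 or self.n_adls < 0:
            raise ConfigError("counts must be nonnegative")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")


def _assemble(
    m: np.ndarray,
    phi: np.ndarray,
    axis: str,
    fs: float,
    rng: np.random.Generator,
    noise_sd_g: float,
    gyro_noise_rads: float,
    gyro_drift_rads: float,
    label: str,
    is_fall: bool,
) -> ImuRecording:
    """Build a recording from scripted SMV magnitude + in-plane rotation angle.

    The gyroscope channel carrying the rotation is the forward
    difference of phi, so its cumulative sum reproduces phi exactly.
    """
    n = len(m)
    dt = 1.0 / fs
    A = np.zeros((n, 3))
    if axis == "z":
        A[:, 0] = m * np.sin(phi)
        A[:, 2] = m * np.cos(phi)
    else:
        A[:, 1] = -m * np.sin(phi)
        A[:, 2] = m * np.cos(phi)
    gdot = np.empty(n)
    gdot[:-1] = np.diff(phi) / dt
    gdot[-1] = gdot[-2] if n > 1 else 0.0
    G = np.zeros((n, 3))
    G[:, 2 if axis == "z" else 1] = gdot

    if noise_sd_g > 0:
        A = A + rng.normal(0.0, noise_sd_g, size=A.shape)
    if gyro_noise_rads > 0:
        G = G + rng.normal(0.0, gyro_noise_rads, size=G.shape)
    G = G + gyro_drift_rads

    t = np.arange(n) * dt
    return ImuRecording(t=t, A=A, G=G, fs=fs, label=label, is_fall=is_fall)


def generate_fall(sc: FallScenario, fs: float = 50.0) -> tuple[ImuRecording, FallTruth]:
    """One scripted fall recording plus its ground-truth annotation."""
    dt = 1.0 / fs
    total = sc.pre_fall_s + sc.freefall_dur_s + sc.impact_rise_s + sc.impact_dur_s + sc.inactivity_s
    n = int(round(total * fs))
    t = np.arange(n) * dt

    t0 = sc.pre_fall_s
    t_rise = t0 + sc.freefall_dur_s
    t_peak = t_rise + sc.impact_rise_s
    t_settle = t_peak + sc.impact_dur_s

    # SMV magnitude profile: 1 -> dip -> spike -> 1
    m = np.ones(n)
    dip = _smoothstep((t - t0) / (0.6 * sc.freefall_dur_s))
    m = 1.0 + (sc.freefall_depth_g - 1.0) * dip
    rise = _smoothstep((t - t_rise) / sc.impact_rise_s)
    m = m + (sc.impact_peak_g - m) * rise
    decay = _smoothstep((t - t_peak) / sc.impact_dur_s)
    m = m + (1.0 - m) * decay
    m[t >= t_settle] = 1.0

    # In-plane rotation: smooth ramp to the net change + decaying tumble
    phi_net = np.deg2rad(sc.orientation_change_deg)
    ramp_dur = sc.freefall_dur_s + sc.impact_rise_s + sc.impact_dur_s
    phi = phi_net * _smoothstep((t - t0) / ramp_dur)
    rel = t - t_peak
    tumble = np.where(
        rel >= 0.0,
        sc.tumble_amp_rad
        * np.sin(2.0 * np.pi * sc.tumble_freq_hz * np.clip(rel, 0.0, None))
        * np.exp(-np.clip(rel, 0.0, None) / sc.tumble_tau_s),
        0.0,
    )
    phi = phi + tumble

    rng = np.random.default_rng(sc.seed)
    rec = _assemble(
        m, phi, sc.axis, fs, rng,
        sc.noise_sd_g, sc.gyro_noise_rads, sc.gyro_drift_rads,
        label="fall", is_fall=True,
    )
    truth = FallTruth(
        impact_time_s=t_peak,
        orientation_change_deg=sc.orientation_change_deg,
        phi=phi,
        axis=sc.axis,
    )
    return rec, truth


def generate_adl(sc: AdlScenario, fs: float = 50.0) -> ImuRecording:
    """One scripted ADL recording of the requested kind."""
    dt = 1.0 / fs
    n = int(round(sc.duration_s * fs))
    t = np.arange(n) * dt
    rng = np.random.default_rng(sc.seed)
    m = np.ones(n)
    phi = np.zeros(n)
    g_extra = 0.0

    if sc.kind == "standing":
        pass
    elif sc.kind in ("walking", "jogging"):
        amp = sc.amplitude_g if sc.amplitude_g is not None else (0.25 if sc.kind == "walking" else 0.4)
        f = sc.freq_hz if sc.freq_hz is not None else (2.0 if sc.kind == "walking" else 2.5)
        m = 1.0 + amp * np.sin(2.0 * np.pi * f * t)
        # mild periodic sway of the gravity direction, far below fall rates
        phi = 0.05 * np.sin(2.0 * np.pi * f * t + 1.0)
    elif sc.kind == "jumping":
        peak = sc.peak_g if sc.peak_g is not None else 2.8
        period = sc.period_s if sc.period_s is not None else 0.5
        m = 1.0 + 0.15 * np.sin(2.0 * np.pi * 3.0 * t)
        for t_spike in np.arange(0.4, sc.duration_s - 0.2, period):
            m = m + (peak - 1.0) * _bump((t - t_spike + 0.06) / 0.12)
        phi = 0.04 * np.sin(2.0 * np.pi * 2.0 * t)
    elif sc.kind == "sitting":
        trans = sc.transition_s if sc.transition_s is not None else 1.0
        change = np.deg2rad(sc.orientation_change_deg if sc.orientation_change_deg is not None else 15.0)
        t1 = sc.duration_s * 0.4
        m = 1.0 - 0.15 * _bump((t - t1) / trans) + 0.3 * _bump((t - t1 - trans) / trans)
        phi = change * _smoothstep((t - t1) / (2.0 * trans))
    elif sc.kind == "lying":
        trans = sc.transition_s if sc.transition_s is not None else 4.0
        change = np.deg2rad(sc.orientation_change_deg if sc.orientation_change_deg is not None else 120.0)
        t1 = sc.duration_s * 0.25
        m = 1.0 + 0.08 * _bump((t - t1) / trans)
        phi = change * _smoothstep((t - t1) / trans)

    return _assemble(
        m, phi, "z", fs, rng,
        sc.noise_sd_g, sc.gyro_noise_rads, sc.gyro_drift_rads,
        label=sc.kind, is_fall=False,
    )


def _fall_scenario(rng: np.random.Generator, seed: int) -> FallScenario:
    return FallScenario(
        pre_fall_s=float(rng.uniform(3.5, 4.5)),
        freefall_depth_g=float(rng.uniform(0.25, 0.55)),
        freefall_dur_s=float(rng.uniform(0.3, 0.45)),
        impact_peak_g=float(rng.uniform(2.6, 3.6)),
        impact_dur_s=float(rng.uniform(0.2, 0.3)),
        inactivity_s=float(rng.uniform(3.6, 4.5)),
        orientation_change_deg=float(rng.uniform(88.0, 115.0)),
        axis="z" if rng.random() < 0.8 else "y",
        seed=seed,
    )


def _adl_scenario(kind: str, rng: np.random.Generator, seed: int) -> AdlScenario:
    jitter = lambda lo, hi: float(rng.uniform(lo, hi))
    kwargs: dict = {"kind": kind, "seed": seed, "duration_s": jitter(11.0, 13.0)}
    if kind == "walking":
        kwargs.update(amplitude_g=jitter(0.18, 0.3), freq_hz=jitter(1.7, 2.3))
    elif kind == "jogging":
        kwargs.update(amplitude_g=jitter(0.3, 0.45), freq_hz=jitter(2.2, 2.8))
    elif kind == "jumping":
        kwargs.update(peak_g=jitter(2.5, 3.0), period_s=jitter(0.45, 0.6))
    elif kind == "sitting":
        kwargs.update(orientation_change_deg=jitter(10.0, 20.0))
    elif kind == "lying":
        kwargs.update(orientation_change_deg=jitter(100.0, 140.0), transition_s=jitter(3.5, 4.5))
    return AdlScenario(**kwargs)


def _adl_counts(mix: dict, n: int) -> dict[str, int]:
    kinds = [k for k in ADL_KINDS if mix.get(k, 0) > 0]
    total_w = sum(mix[k] for k in kinds)
    counts = {k: int(np.floor(mix[k] / total_w * n)) for k in kinds}
    short = n - sum(counts.values())
    for k in kinds[:short]:
        counts[k] += 1
    return counts


def generate_dataset(
    spec: DatasetSpec,
) -> tuple[list[ImuRecording], pd.DataFrame]:
    """A labelled corpus plus its manifest; identical given identical spec.

    Every recording draws its scenario parameters and noise from a
    seed derived deterministically from the master seed and its index,
    so recordings are independent of one another.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_falls + spec.n_adls)
    recs: list[ImuRecording] = []
    rows = []
    idx = 0
    for _ in range(spec.n_falls):
        child = children[idx]
        rec_seed = int(child.generate_state(1)[0])
        rng = np.random.default_rng(child)
        sc = _fall_scenario(rng, rec_seed)
        rec, truth = generate_fall(sc, spec.fs)
        rec = replace(rec, subject_id=f"r{idx:04d}", label=f"fall_{sc.axis}")
        recs.append(rec)
        rows.append(
            {
                "recording": rec.subject_id, "label": rec.label, "is_fall": True,
                "seed": rec_seed, "impact_time_s": truth.impact_time_s,
                "impact_peak_g": sc.impact_peak_g,
                "orientation_change_deg": sc.orientation_change_deg,
            }
        )
        idx += 1
    for kind, count in _adl_counts(spec.adl_mix, spec.n_adls).items():
        for _ in range(count):
            child = children[idx]
            rec_seed = int(child.generate_state(1)[0])
            rng = np.random.default_rng(child)
            sc = _adl_scenario(kind, rng, rec_seed)
            rec = generate_adl(sc, spec.fs)
            rec = replace(rec, subject_id=f"r{idx:04d}")
            recs.append(rec)
            rows.append(
                {
                    "recording": rec.subject_id, "label": kind, "is_fall": False,
                    "seed": rec_seed, "impact_time_s": np.nan,
                    "impact_peak_g": np.nan, "orientation_change_deg": np.nan,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    return recs, manifest


def save_dataset(recs: list[ImuRecording], manifest: pd.DataFrame, out_dir: str | Path) -> None:
    """Write a corpus as generic-dialect CSVs plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recs:
        write_recording(rec, out_dir / f"{rec.subject_id}.csv")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
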