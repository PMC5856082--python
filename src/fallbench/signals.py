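"""Core IMU data model, dataset dialects, and the preprocessing chain.

Canonical units are g for acceleration and rad/s for angular velocity.
The standard preprocessing applied before any detector runs is a
downsample to 50 Hz followed by a 3-sample running median.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import median_filter
from scipy.signal import resample_poly

from .errors import ConfigError, ContractError, DataError, FormatError

log = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665  # m/s^2 per g

#: Upper edge of the human-movement frequency band (Hz).
HUMAN_MOVEMENT_BAND_HZ = 20.0

#: Default processing rate of the pipeline (Hz).
DEFAULT_FS_HZ = 50.0

_T_TOL = 1e-9


def min_sampling_rate_hz(band_limit_hz: float = HUMAN_MOVEMENT_BAND_HZ) -> float:
    """Minimum sampling rate satisfying the sampling theorem for a band-limited signal.

    Used as the validated lower bound for the pipeline's sampling-rate
    configuration: processing below twice the signal band aliases movement
    content.
    """
    if band_limit_hz <= 0:
        raise ConfigError(f"band limit must be positive, got {band_limit_hz}")
    return 2.0 * band_limit_hz


@dataclass
class ImuRecording:
    """A labelled tri-axial accelerometer + gyroscope time series.

    Attributes
    ----------
    t : (n,) float array
        Sample times in seconds, uniformly spaced at 1/fs.
    A : (n, 3) float array
        Acceleration in g.
    G : (n, 3) float array
        Angular velocity in rad/s.
    fs : float
        Sampling rate in Hz.
    label : str
        Activity subtype (fall subtype or ADL subtype).
    is_fall : bool
        Binary class label.
    """

    t: np.ndarray
    A: np.ndarray
    G: np.ndarray
    fs: float
    subject_id: str = ""
    label: str = ""
    is_fall: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.fs <= 0:
            raise DataError(f"fs must be positive, got {self.fs}")
        n = self.t.shape[0]
        if self.A.shape != (n, 3) or self.G.shape != (n, 3):
            raise DataError(
                f"A and G must both be ({n}, 3); got {self.A.shape} and {self.G.shape}"
            )
        if not (np.isfinite(self.t).all() and np.isfinite(self.A).all() and np.isfinite(self.G).all()):
            raise DataError("recording contains non-finite samples")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError("sample times are not strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > _T_TOL:
                raise DataError(
                    f"sample times are not uniform at 1/fs={1.0 / self.fs!r}"
                )

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def smv(self) -> np.ndarray:
        """Signal magnitude vector of the acceleration, in g."""
        return magnitude(self.A)


@dataclass(frozen=True)
class Window:
    """Half-open sample-index interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ContractError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Dataset dialects
# ---------------------------------------------------------------------------

GENERIC_COLUMNS = {
    "time": "time_s",
    "ax": "ax_g",
    "ay": "ay_g",
    "az": "az_g",
    "gx": "gx_rads",
    "gy": "gy_rads",
    "gz": "gz_rads",
}


@dataclass(frozen=True)
class DatasetDialect:
    """Column layout and units of a CSV corpus.

    ``acc_unit`` is one of ``{"g", "ms2"}``; ``gyro_unit`` one of
    ``{"rads", "degs"}``; ``time_unit`` one of ``{"s", "ms", "ns", None}``
    (None means no time column: timestamps are synthesized from
    ``native_fs``).
    """

    name: str
    columns: dict = field(default_factory=lambda: dict(GENERIC_COLUMNS))
    acc_unit: str = "g"
    gyro_unit: str = "rads"
    native_fs: float | None = None
    time_unit: str | None = "s"
    sep: str = ","

    def __post_init__(self) -> None:
        if self.acc_unit not in ("g", "ms2"):
            raise ConfigError(f"unknown acceleration unit {self.acc_unit!r}")
        if self.gyro_unit not in ("rads", "degs"):
            raise ConfigError(f"unknown gyroscope unit {self.gyro_unit!r}")
        if self.time_unit is None and (self.native_fs is None or self.native_fs <= 0):
            raise ConfigError("a dialect without a time column needs a positive native_fs")


#: Built-in dialects. The three named corpora follow their published CSV
#: layouts; only ``generic`` is exercised by the test suite (the public
#: downloads are not required anywhere).
DIALECTS: dict[str, DatasetDialect] = {
    "generic": DatasetDialect(name="generic"),
    "mobiact": DatasetDialect(
        name="mobiact",
        columns={
            "time": "timestamp",
            "ax": "acc_x", "ay": "acc_y", "az": "acc_z",
            "gx": "gyro_x", "gy": "gyro_y", "gz": "gyro_z",
        },
        acc_unit="ms2",
        gyro_unit="rads",
        native_fs=100.0,
        time_unit="ns",
    ),
    "dlr": DatasetDialect(
        name="dlr",
        columns={
            "time": "time",
            "ax": "acc_x", "ay": "acc_y", "az": "acc_z",
            "gx": "gyr_x", "gy": "gyr_y", "gz": "gyr_z",
        },
        acc_unit="ms2",
        gyro_unit="rads",
        native_fs=100.0,
        time_unit="s",
    ),
    "umafall": DatasetDialect(
        name="umafall",
        columns={
            "time": "TimeStamp",
            "ax": "X-Axis", "ay": "Y-Axis", "az": "Z-Axis",
            "gx": "X-Gyro", "gy": "Y-Gyro", "gz": "Z-Gyro",
        },
        acc_unit="g",
        gyro_unit="degs",
        native_fs=200.0,
        time_unit="ms",
        sep=";",
    ),
}


def dialects_from_yaml(path: str | Path) -> dict[str, DatasetDialect]:
    """Load user-defined dialects from a YAML mapping of name -> fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, cfg in raw.items():
        out[name] = DatasetDialect(name=name, **cfg)
    return out


def load_recording(path: str | Path, dialect: DatasetDialect | str = "generic") -> ImuRecording:
    """Read one CSV recording under the given dialect into canonical units.

    A JSON sidecar ``<path>.json`` (written by :func:`write_recording`)
    supplies ``subject_id``/``label``/``fs`` when present; otherwise the
    label falls back to the file-name convention (a stem containing
    ``fall`` marks a fall).
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep)
    cols = dialect.columns
    for key in ("ax", "ay", "az", "gx", "gy", "gz"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"{path.name}: missing column {cols[key]!r} required by dialect {dialect.name!r}"
            )
    A = df[[cols["ax"], cols["ay"], cols["az"]]].to_numpy(dtype=float)
    G = df[[cols["gx"], cols["gy"], cols["gz"]]].to_numpy(dtype=float)
    if dialect.acc_unit == "ms2":
        A = A / STANDARD_GRAVITY
    if dialect.gyro_unit == "degs":
        G = np.deg2rad(G)

    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if dialect.time_unit is not None:
        tcol = cols.get("time")
        if tcol not in df.columns:
            raise FormatError(
                f"{path.name}: missing time column {tcol!r} required by dialect {dialect.name!r}"
            )
        scale = {"s": 1.0, "ms": 1e-3, "ns": 1e-9}[dialect.time_unit]
        t_raw = df[tcol].to_numpy(dtype=float) * scale
        if np.any(np.diff(t_raw) <= 0):
            raise DataError(f"{path.name}: timestamps are not strictly increasing")
        t_raw = t_raw - t_raw[0]
        if len(t_raw) >= 2:
            fs = float(meta.get("fs") or round(1.0 / np.median(np.diff(t_raw)), 6))
        else:
            fs = float(meta.get("fs") or dialect.native_fs or 1.0)
        # Rebuild a uniform grid at the inferred rate; real corpora jitter.
        t = np.arange(len(t_raw)) / fs
    else:
        fs = float(meta.get("fs") or dialect.native_fs)
        t = np.arange(len(A)) / fs

    stem = path.stem.lower()
    label = meta.get("label", path.stem)
    is_fall = bool(meta.get("is_fall", "fall" in stem))
    return ImuRecording(
        t=t, A=A, G=G, fs=fs,
        subject_id=str(meta.get("subject_id", "")),
        label=label, is_fall=is_fall,
    )


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as a generic-dialect CSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.t,
            "ax_g": rec.A[:, 0], "ay_g": rec.A[:, 1], "az_g": rec.A[:, 2],
            "gx_rads": rec.G[:, 0], "gy_rads": rec.G[:, 1], "gz_rads": rec.G[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "is_fall": rec.is_fall,
                "fs": rec.fs,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def magnitude(A: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of a (n, 3) vector sequence.

    The squared components are summed in sorted order, so the result is
    bit-for-bit invariant under component permutations and sign flips.
    """
    A = np.asarray(A, dtype=float)
    sq = np.sort(A * A, axis=-1)
    return np.sqrt(sq.sum(axis=-1))


def median_filter3(rec: ImuRecording) -> ImuRecording:
    """3-sample running median on every channel; edges replicate."""
    if len(rec) < 1:
        raise ContractError("median_filter3 requires at least one sample")
    A = median_filter(rec.A, size=(3, 1), mode="nearest")
    G = median_filter(rec.G, size=(3, 1), mode="nearest")
    return replace(rec, A=A, G=G)


def resample(
    rec: ImuRecording,
    target_fs: float,
    *,
    upsample: bool = False,
    method: str = "poly",
) -> ImuRecording:
    """Resample every channel to ``target_fs``.

    ``method="poly"`` uses anti-aliased polyphase decimation for integer
    ratios and linear interpolation otherwise; ``method="subsample"``
    takes every q-th sample (integer ratios only), which commutes with
    pointwise operations such as :func:`magnitude`.
    """
    if target_fs <= 0:
        raise ConfigError(f"target_fs must be positive, got {target_fs}")
    if len(rec) == 0:
        raise ContractError("cannot resample an empty recording")
    if target_fs > rec.fs and not upsample:
        raise ConfigError(
            f"target_fs={target_fs} exceeds recording rate {rec.fs}; "
            "pass upsample=True to allow it"
        )
    if math.isclose(target_fs, rec.fs):
        return rec

    n = len(rec)
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    integer = abs(ratio - q) < 1e-9 and q >= 1

    if integer and method == "subsample":
        A, G = rec.A[::q], rec.G[::q]
    elif integer and not upsample:
        if method != "poly":
            raise ConfigError(f"unknown resampling method {method!r}")
        A = resample_poly(rec.A, up=1, down=q, axis=0, padtype="line")
        G = resample_poly(rec.G, up=1, down=q, axis=0, padtype="line")
    else:
        n_new = int(np.ceil(n * target_fs / rec.fs))
        t_new = rec.t[0] + np.arange(n_new) / target_fs
        A = np.column_stack([np.interp(t_new, rec.t, rec.A[:, i]) for i in range(3)])
        G = np.column_stack([np.interp(t_new, rec.t, rec.G[:, i]) for i in range(3)])
    t = rec.t[0] + np.arange(len(A)) / target_fs
    return replace(rec, t=t, A=A, G=G, fs=float(target_fs))


def sliding_windows(n: int, width_s: float, stride_s: float, fs: float) -> list[Window]:
    """Half-open windows of ``width_s`` seconds every ``stride_s`` seconds.

    The last partial window is dropped; a recording shorter than one
    window yields an empty list.
    """
    width = int(round(width_s * fs))
    stride = max(1, int(round(stride_s * fs)))
    if width < 1:
        raise ContractError("window width must cover at least one sample")
    if width > n:
        return []
    return [Window(s, s + width) for s in range(0, n - width + 1, stride)]


def preprocess(
    rec: ImuRecording,
    target_fs: float = DEFAULT_FS_HZ,
    *,
    median_first: bool = False,
) -> ImuRecording:
    """Standard chain: downsample to ``target_fs`` then 3-sample median.

    Recordings sampled below ``target_fs`` are kept at their native rate
    with a warning (the pipeline never upsamples). ``median_first``
    swaps the two steps.
    """
    if target_fs < min_sampling_rate_hz():
        log.warning(
            "target_fs=%.1f Hz is below the %.0f Hz bound implied by the "
            "%.0f Hz movement band",
            target_fs, min_sampling_rate_hz(), HUMAN_MOVEMENT_BAND_HZ,
        )
    steps = []
    if rec.fs > target_fs:
        steps.append(lambda r: resample(r, target_fs))
    elif rec.fs < target_fs:
        log.warning(
            "recording rate %.1f Hz below target %.1f Hz; keeping native rate",
            rec.fs, target_fs,
        )
    steps.append(median_filter3)
    if median_first:
        steps.reverse()
    for step in steps:
        rec = step(rec)
    return rec
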