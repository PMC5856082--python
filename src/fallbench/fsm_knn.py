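"""Single-accelerometer fall detector: FSM candidate gating plus kNN refinement.

A finite state machine over the acceleration magnitude (SMV) models the
canonical fall phases: an impact peak above SMV_PEAK followed by
post-impact inactivity (SMV staying near 1 g inside the
[AT_LOW, AT_HIGH] window after the peak). Surviving candidates yield an
11-dimensional time/frequency feature vector from the
[FS_LOW, FS_HIGH] segment around the peak, classified by a kNN model
trained on labelled recordings.

The exact feature list of the original detector is not published; the
set below is a documented stand-in computable from SMV alone
(see FEATURE_NAMES).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from scipy.stats import kurtosis, skew

from .errors import ContractError, FallbenchError
from .signals import ImuRecording, Window

log = logging.getLogger(__name__)

FEATURE_NAMES = (
    "mean",
    "std",
    "min",
    "max",
    "range",
    "skewness",
    "kurtosis",
    "sma",            # mean |SMV - 1 g|
    "n_above_peak",   # samples above the candidate threshold
    "dom_freq_hz",    # periodogram argmax of the detrended segment
    "low_band_frac",  # spectral energy fraction below 5 Hz
)

LOW_BAND_HZ = 5.0


@dataclass(frozen=True)
class FsmKnnParams:
    """FSM thresholds/timers and classifier size.

    Timers are in milliseconds relative to the impact peak; ``fs_low``
    is negative (the feature segment starts before the peak).
    """

    smv_peak: float
    at_low_ms: float = 1423.0
    at_high_ms: float = 2702.0
    fs_low_ms: float = -2170.0
    fs_high_ms: float = 1155.0
    k: int = 7
    inactivity_band_g: float = 0.15

    def __post_init__(self) -> None:
        if not self.at_low_ms < self.at_high_ms:
            raise ContractError("at_low_ms must be below at_high_ms")
        if not self.fs_low_ms < 0 < self.fs_high_ms:
            raise ContractError("feature segment must straddle the peak (fs_low < 0 < fs_high)")
        if self.k < 1 or self.k % 2 == 0:
            raise ContractError(f"k must be a positive odd integer, got {self.k}")


@dataclass(frozen=True)
class CandidateEvent:
    peak_index: int
    peak_time: float
    peak_value: float
    feature_segment: Window


def fsm_candidates(smv: np.ndarray, fs: float, p: FsmKnnParams) -> list[CandidateEvent]:
    """Candidate impacts: supra-threshold SMV runs passing the inactivity check.

    Each contiguous run of samples above ``smv_peak`` contributes its
    argmax as the impact peak. The candidate survives when the mean of
    |SMV - 1 g| over [peak + at_low, peak + at_high] stays inside the
    inactivity band. After an emitted candidate, later peaks before
    peak + at_high are suppressed (refractory). Candidates whose
    feature segment leaves the recording are dropped.
    """
    smv = np.asarray(smv, dtype=float)
    n = len(smv)
    above = smv > p.smv_peak
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)

    at_lo = int(round(p.at_low_ms * 1e-3 * fs))
    at_hi = int(round(p.at_high_ms * 1e-3 * fs))
    fs_lo = int(round(p.fs_low_ms * 1e-3 * fs))
    fs_hi = int(round(p.fs_high_ms * 1e-3 * fs))

    out: list[CandidateEvent] = []
    refractory_until = -1
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(smv[s:e]))
        if peak <= refractory_until:
            continue
        w_lo, w_hi = peak + at_lo, peak + at_hi
        if w_hi > n:
            log.debug("candidate at %d dropped: inactivity window out of range", peak)
            continue
        if float(np.mean(np.abs(smv[w_lo:w_hi] - 1.0))) >= p.inactivity_band_g:
            continue
        seg_lo, seg_hi = peak + fs_lo, peak + fs_hi
        if seg_lo < 0 or seg_hi > n:
            log.debug("candidate at %d dropped: feature segment out of range", peak)
            continue
        out.append(
            CandidateEvent(
                peak_index=peak,
                peak_time=peak / fs,
                peak_value=float(smv[peak]),
                feature_segment=Window(seg_lo, seg_hi),
            )
        )
        refractory_until = peak + at_hi
    return out


def extract_features(
    smv_segment: np.ndarray, fs: float, peak_g: float = 1.8
) -> np.ndarray:
    """Fixed-order 11-feature vector from an SMV segment (see FEATURE_NAMES)."""
    x = np.asarray(smv_segment, dtype=float)
    if x.size < 8:
        raise ContractError(f"feature segment needs >= 8 samples, got {x.size}")
    mu = float(x.mean())
    sd = float(x.std())
    if sd > 0:
        skw = float(skew(x))
        kur = float(kurtosis(x))
    else:
        skw = kur = 0.0
    detrended = x - mu
    freqs, pxx = periodogram(detrended, fs=fs)
    total = float(pxx.sum())
    if total > 0:
        dom = float(freqs[int(np.argmax(pxx))])
        low_frac = float(pxx[freqs <= LOW_BAND_HZ].sum() / total)
    else:
        dom, low_frac = 0.0, 0.0
    return np.array(
        [
            mu,
            sd,
            float(x.min()),
            float(x.max()),
            float(x.max() - x.min()),
            skw,
            kur,
            float(np.mean(np.abs(x - 1.0))),
            float(np.count_nonzero(x > peak_g)),
            dom,
            low_frac,
        ]
    )


@dataclass
class KnnModel:
    """Standardized training set for majority-vote kNN."""

    X: np.ndarray           # (m, d) z-scored features
    y: np.ndarray           # (m,) bool, True = fall
    mu: np.ndarray
    sigma: np.ndarray
    k: int = 7
    feature_names: tuple = FEATURE_NAMES


def knn_fit(features: np.ndarray, labels: np.ndarray, k: int = 7) -> KnnModel:
    """Standardize features (constant features get scale 1) and store the set."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ContractError("features must be (m, d) with one label per row")
    if y.all() or not y.any():
        raise FallbenchError("kNN training set must contain both classes")
    if X.shape[0] < k:
        raise ContractError(f"need at least k={k} training points, got {X.shape[0]}")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma = np.where(sigma == 0.0, 1.0, sigma)
    return KnnModel(X=(X - mu) / sigma, y=y, mu=mu, sigma=sigma, k=k)


def knn_classify(model: KnnModel, x: np.ndarray, k: int | None = None) -> bool:
    """Majority label of the k nearest training points (Euclidean, z-scored).

    Distance ties at the k-th position are broken by lower training
    index (stable sort).
    """
    k = model.k if k is None else k
    if k > model.X.shape[0]:
        raise ContractError("k exceeds training-set size")
    z = (np.asarray(x, dtype=float) - model.mu) / model.sigma
    d = np.linalg.norm(model.X - z, axis=1)
    order = np.argsort(d, kind="stable")[:k]
    votes = int(np.count_nonzero(model.y[order]))
    return votes * 2 > k


def features_for_smv(smv: np.ndarray, fs: float, p: FsmKnnParams) -> list[np.ndarray]:
    """Training feature vectors from one SMV track.

    Candidate segments are used where the FSM fires; a track with no
    candidate contributes the segment centred on its global SMV peak
    (skipped if it leaves the track), so ADL recordings still provide
    negative examples.
    """
    segs = [c.feature_segment for c in fsm_candidates(smv, fs, p)]
    if not segs:
        peak = int(np.argmax(smv))
        lo = peak + int(round(p.fs_low_ms * 1e-3 * fs))
        hi = peak + int(round(p.fs_high_ms * 1e-3 * fs))
        if lo < 0 or hi > len(smv):
            return []
        segs = [Window(lo, hi)]
    return [extract_features(smv[w.start:w.end], fs, peak_g=p.smv_peak) for w in segs]


def training_features(
    recordings: list[ImuRecording], p: FsmKnnParams
) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors + labels for fitting, one or more per recording."""
    rows, labels = [], []
    for rec in recordings:
        vecs = features_for_smv(rec.smv(), rec.fs, p)
        rows.extend(vecs)
        labels.extend([rec.is_fall] * len(vecs))
    if not rows:
        raise FallbenchError("no usable feature segments in the training recordings")
    return np.vstack(rows), np.asarray(labels, dtype=bool)


def fit(recordings: list[ImuRecording], p: FsmKnnParams) -> KnnModel:
    """Fit the kNN stage from labelled recordings."""
    X, y = training_features(recordings, p)
    return knn_fit(X, y, k=p.k)


def detect(rec: ImuRecording, p: FsmKnnParams, model: KnnModel) -> list[float]:
    """Detection times (s): FSM candidates classified as falls by the kNN."""
    smv = rec.smv()
    out = []
    for cand in fsm_candidates(smv, rec.fs, p):
        w = cand.feature_segment
        x = extract_features(smv[w.start:w.end], rec.fs, peak_g=p.smv_peak)
        if knn_classify(model, x, k=p.k):
            out.append(cand.peak_time)
    return out
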