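"""Cross-validated random threshold search with ROC-distance selection.

For every fold of a stratified 10-fold split, 10 candidate threshold
sets are drawn uniformly from the per-algorithm search ranges,
evaluated on the fold's training recordings (recording-level decision:
any detection marks the recording positive), and the candidate closest
to (0, 1) on the sensitivity vs. (1 - specificity) plane wins. The
winner is scored on the fold's test recordings; the ten fold confusion
matrices sum into the cumulative matrix, and the overall best threshold
set is the ROC-closest of the ten fold winners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import feature_cascade, fsm_knn, pattern_match, two_phase
from .errors import ConfigError, ContractError, FallbenchError
from .evaluation import ConfusionMatrix, MetricSet, metrics
from .signals import ImuRecording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchRange:
    """Uniform sampling interval for one threshold."""

    name: str
    low: float
    high: float
    integer: bool = False
    odd: bool = False

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise ConfigError(f"range for {self.name!r} must have low <= high")

    def sample(self, rng: np.random.Generator) -> float | int:
        if self.odd:
            lo = int(np.ceil(self.low))
            lo += (lo + 1) % 2
            values = np.arange(lo, int(np.floor(self.high)) + 1, 2)
            return int(rng.choice(values))
        if self.integer:
            return int(rng.integers(int(np.ceil(self.low)), int(np.floor(self.high)) + 1))
        return float(rng.uniform(self.low, self.high))


#: Published search ranges of the four algorithms (thresholds in g,
#: degrees, rad/s, rad/s^2; timers in ms).
DEFAULT_RANGES: dict[str, list[SearchRange]] = {
    "alg1": [
        SearchRange("smv_ff", 0.7, 0.9),
        SearchRange("smv_ip", 1.5, 1.7),
        SearchRange("av_ff", 0.3, 0.7),
        SearchRange("av_ip", 0.7, 1.1),
    ],
    "alg2": [
        SearchRange("sv", 1.7, 2.3),
        SearchRange("av", 21.0, 23.0),
        SearchRange("ca", 42.0, 46.0),
        SearchRange("sv_g", 2.0, 2.4),
        SearchRange("sv_ga", 36.0, 40.0),
    ],
    "alg3": [
        SearchRange("th_ca", 0.4, 0.8),
        SearchRange("th_g", 0.3, 0.7),
        SearchRange("th_cg", 0.2, 0.6),
    ],
    "alg4": [
        SearchRange("smv_peak", 1.8, 2.2),
        SearchRange("at_low_ms", 1000, 2000, integer=True),
        SearchRange("at_high_ms", 2500, 3000, integer=True),
        SearchRange("fs_low_ms", -2500, -1500, integer=True),
        SearchRange("fs_high_ms", 500, 1500, integer=True),
        SearchRange("k", 1, 9, integer=True, odd=True),
    ],
}

#: Published optimum threshold sets (found on the largest corpus).
OPTIMUM_THRESHOLDS: dict[str, dict] = {
    "alg1": {"smv_ff": 0.8362, "smv_ip": 1.5731, "av_ff": 0.5633, "av_ip": 0.7387},
    "alg2": {"sv": 2.0422, "av": 21.4522, "ca": 42.6328, "sv_g": 2.3986, "sv_ga": 39.6284},
    "alg3": {"th_ca": 0.7684, "th_g": 0.3331, "th_cg": 0.3216},
    "alg4": {
        "smv_peak": 1.8618, "at_low_ms": 1423, "at_high_ms": 2702,
        "fs_low_ms": -2170, "fs_high_ms": 1155, "k": 7,
    },
}


def sample_thresholds(
    ranges: list[SearchRange], n_sets: int, rng: np.random.Generator | int
) -> list[dict]:
    """Draw n_sets independent threshold sets, one value per range."""
    if n_sets < 1:
        raise ContractError("n_sets must be at least 1")
    if not ranges:
        raise ConfigError("no search ranges given")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [{r.name: r.sample(rng) for r in ranges} for _ in range(n_sets)]


def roc_select(candidates: list[tuple[dict, float, float]]) -> int:
    """Index of the candidate minimizing distance to (0, 1) on the ROC plane.

    Candidates are (threshold set, sensitivity, specificity); ties keep
    the earliest index.
    """
    if not candidates:
        raise ContractError("roc_select needs at least one candidate")
    best, best_d = 0, np.inf
    for i, (_, sens, spec) in enumerate(candidates):
        d = float(np.hypot(1.0 - spec, 1.0 - sens))
        if d < best_d:
            best, best_d = i, d
    return best


def stratified_folds(
    labels: np.ndarray, n_folds: int = 10, rng: np.random.Generator | int = 0
) -> np.ndarray:
    """Fold index (0..n_folds-1) per recording, class-balanced within +-1."""
    labels = np.asarray(labels, dtype=bool)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    assign = np.empty(len(labels), dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        if 0 < len(idx) < n_folds:
            raise FallbenchError(
                f"class {cls} has only {len(idx)} recordings; use fewer than "
                f"{n_folds} folds"
            )
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % n_folds
    return assign


# ---------------------------------------------------------------------------
# Detector adapters
# ---------------------------------------------------------------------------

class DetectorAdapter:
    """Uniform interface the CV harness drives.

    ``prepare`` caches per-recording signal products once; ``fold_setup``
    derives per-fold training context (e.g. the fall pattern);
    ``fit`` turns a threshold set into a ready model; ``detect``
    returns detection times.
    """

    name: str = ""

    def prepare(self, rec: ImuRecording) -> dict:
        raise NotImplementedError

    def fold_setup(self, prepared_train: list[dict]) -> object:
        return None

    def fit(self, fold_ctx: object, prepared_train: list[dict], params: dict) -> object:
        return None

    def detect(self, prepared: dict, params: dict, model: object) -> list[float]:
        raise NotImplementedError


class TwoPhaseAdapter(DetectorAdapter):
    name = "alg1"

    def __init__(self, alpha: float = 0.95):
        self.alpha = alpha

    def prepare(self, rec):
        cfg = two_phase.ComplementaryFilterConfig(alpha=self.alpha, dt=1.0 / rec.fs)
        return {
            "smv": rec.smv(),
            "av": two_phase.vertical_series(rec, cfg),
            "fs": rec.fs,
            "is_fall": rec.is_fall,
        }

    def detect(self, prepared, params, model):
        th = two_phase.TwoPhaseThresholds(**params)
        return two_phase.detect_two_phase(prepared["smv"], prepared["av"], prepared["fs"], th)


class CascadeAdapter(DetectorAdapter):
    name = "alg2"

    def __init__(self, cutoff_hz=feature_cascade.DEFAULT_CUTOFF_HZ,
                 window_s=feature_cascade.DEFAULT_WINDOW_S,
                 stride_s=feature_cascade.DEFAULT_STRIDE_S):
        self.cutoff_hz = cutoff_hz
        self.window_s = window_s
        self.stride_s = stride_s

    def prepare(self, rec):
        feats = feature_cascade.all_window_features(
            rec, self.window_s, self.stride_s, self.cutoff_hz
        )
        return {"features": feats, "is_fall": rec.is_fall}

    def detect(self, prepared, params, model):
        th = feature_cascade.CascadeThresholds(**params)
        return feature_cascade.detect_from_features(prepared["features"], th)


class _PatternFoldCtx:
    def __init__(self, pattern, stride_s):
        self.pattern = pattern
        self.stride_s = stride_s
        self._scores: dict[int, list] = {}

    def scores(self, prepared):
        key = id(prepared)
        if key not in self._scores:
            self._scores[key] = pattern_match.segment_scores(
                prepared["rec"], self.pattern, self.stride_s
            )
        return self._scores[key]


class PatternAdapter(DetectorAdapter):
    name = "alg3"

    def __init__(self, stride_s=pattern_match.DEFAULT_STRIDE_S):
        self.stride_s = stride_s

    def prepare(self, rec):
        return {"rec": rec, "is_fall": rec.is_fall}

    def fold_setup(self, prepared_train):
        falls = [p["rec"] for p in prepared_train if p["is_fall"]]
        return _PatternFoldCtx(pattern_match.build_pattern(falls), self.stride_s)

    def detect(self, prepared, params, model):
        th = pattern_match.PatternThresholds(**params)
        return pattern_match.detect_from_scores(model.scores(prepared), th)

    def fit(self, fold_ctx, prepared_train, params):
        return fold_ctx


class FsmKnnAdapter(DetectorAdapter):
    name = "alg4"

    def prepare(self, rec):
        return {"smv": rec.smv(), "fs": rec.fs, "is_fall": rec.is_fall}

    def fit(self, fold_ctx, prepared_train, params):
        p = _alg4_params(params)
        rows, labels = [], []
        for prep in prepared_train:
            for x in fsm_knn.features_for_smv(prep["smv"], prep["fs"], p):
                rows.append(x)
                labels.append(prep["is_fall"])
        return fsm_knn.knn_fit(np.vstack(rows), np.asarray(labels, dtype=bool), k=p.k)

    def detect(self, prepared, params, model):
        p = _alg4_params(params)
        smv, fs = prepared["smv"], prepared["fs"]
        out = []
        for cand in fsm_knn.fsm_candidates(smv, fs, p):
            w = cand.feature_segment
            x = fsm_knn.extract_features(smv[w.start:w.end], fs, peak_g=p.smv_peak)
            if fsm_knn.knn_classify(model, x, k=p.k):
                out.append(cand.peak_time)
        return out


def _alg4_params(params: dict) -> fsm_knn.FsmKnnParams:
    return fsm_knn.FsmKnnParams(**params)


ADAPTERS = {
    "alg1": TwoPhaseAdapter,
    "alg2": CascadeAdapter,
    "alg3": PatternAdapter,
    "alg4": FsmKnnAdapter,
}


def get_adapter(name: str) -> DetectorAdapter:
    if name not in ADAPTERS:
        raise ConfigError(f"unknown algorithm {name!r}; choose from {sorted(ADAPTERS)}")
    return ADAPTERS[name]()


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold_index: int
    best_thresholds: dict
    train_sensitivity: float
    train_specificity: float
    test_confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "best_thresholds": self.best_thresholds,
            "train_sensitivity": self.train_sensitivity,
            "train_specificity": self.train_specificity,
            "test_confusion": self.test_confusion.to_dict(),
        }


@dataclass
class CvResult:
    algorithm: str
    folds: list[FoldResult]
    cumulative_confusion: ConfusionMatrix
    overall_best_thresholds: dict

    @property
    def fold_metrics(self) -> list[MetricSet]:
        return [metrics(f.test_confusion) for f in self.folds]

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "folds": [f.to_dict() for f in self.folds],
            "cumulative_confusion": self.cumulative_confusion.to_dict(),
            "overall_best_thresholds": self.overall_best_thresholds,
            "fold_metrics": [m.to_dict() for m in self.fold_metrics],
        }


def _flags(adapter, prepared_list, params, model) -> np.ndarray:
    out = np.zeros(len(prepared_list), dtype=bool)
    for i, prep in enumerate(prepared_list):
        try:
            out[i] = len(adapter.detect(prep, params, model)) > 0
        except FallbenchError as exc:
            # robustness contract: a failing recording counts as "no detection"
            log.warning("detector %s failed on a recording: %s", adapter.name, exc)
    return out


def _confusion(flags: np.ndarray, is_fall: np.ndarray) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=int(np.count_nonzero(flags & is_fall)),
        tn=int(np.count_nonzero(~flags & ~is_fall)),
        fp=int(np.count_nonzero(flags & ~is_fall)),
        fn=int(np.count_nonzero(~flags & is_fall)),
    )


def _sens_spec(cm: ConfusionMatrix) -> tuple[float, float]:
    m = metrics(cm)
    return (m.sensitivity if m.sensitivity is not None else 0.0,
            m.specificity if m.specificity is not None else 0.0)


def cross_validate(
    recordings: list[ImuRecording],
    algorithm: str | DetectorAdapter,
    ranges: list[SearchRange] | None = None,
    n_sets: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> CvResult:
    """Run the full threshold-selection protocol on a labelled corpus.

    Thresholds are chosen on each fold's training recordings only; the
    fold winner is then scored once on the held-out recordings.
    """
    adapter = get_adapter(algorithm) if isinstance(algorithm, str) else algorithm
    if ranges is None:
        ranges = DEFAULT_RANGES[adapter.name]
    is_fall = np.array([r.is_fall for r in recordings], dtype=bool)

    master = np.random.SeedSequence(seed)
    fold_seed, *cand_seeds = master.spawn(1 + n_folds)
    folds = stratified_folds(is_fall, n_folds, np.random.default_rng(fold_seed))

    prepared = [adapter.prepare(r) for r in recordings]
    fold_results: list[FoldResult] = []
    cumulative = ConfusionMatrix()
    for f in range(n_folds):
        test_mask = folds == f
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        prep_train = [prepared[i] for i in train_idx]
        prep_test = [prepared[i] for i in test_idx]

        ctx = adapter.fold_setup(prep_train)
        rng = np.random.default_rng(cand_seeds[f])
        candidates = sample_thresholds(ranges, n_sets, rng)
        scored = []
        models = []
        for params in candidates:
            model = adapter.fit(ctx, prep_train, params)
            models.append(model)
            cm = _confusion(_flags(adapter, prep_train, params, model), is_fall[train_idx])
            sens, spec = _sens_spec(cm)
            scored.append((params, sens, spec))
        win = roc_select(scored)
        params, sens, spec = scored[win]
        test_cm = _confusion(
            _flags(adapter, prep_test, params, models[win]), is_fall[test_idx]
        )
        fold_results.append(
            FoldResult(
                fold_index=f + 1,
                best_thresholds=params,
                train_sensitivity=sens,
                train_specificity=spec,
                test_confusion=test_cm,
            )
        )
        cumulative = cumulative + test_cm

    overall_idx = roc_select(
        [(fr.best_thresholds, fr.train_sensitivity, fr.train_specificity) for fr in fold_results]
    )
    return CvResult(
        algorithm=adapter.name,
        folds=fold_results,
        cumulative_confusion=cumulative,
        overall_best_thresholds=fold_results[overall_idx].best_thresholds,
    )
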