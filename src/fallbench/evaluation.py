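"""Performance metrics and the rank-based algorithm comparison.

The comparison ranks per-fold metric values of k algorithms inside each
dataset block, decomposes the ranks in a two-way ANOVA-style table
(Columns = algorithms, Interaction = dataset x algorithm, Error,
Total), forms a chi-square statistic from the Columns sum of squares
with tie correction, and follows a rejected null with the Nemenyi
post-hoc test on average ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, rankdata

from .errors import ConfigError, ContractError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ContractError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity/specificity/precision/F1; None marks an undefined ratio."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None

    def __getitem__(self, name: str) -> float | None:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1")


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, precision, and F1 from the confusion counts.

    Any metric whose denominator is zero is reported as None and
    propagates as missing rather than silently becoming 0.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    if prec is None or sens is None or (prec + sens) == 0.0:
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricSet(sens, spec, prec, f1)


# ---------------------------------------------------------------------------
# Friedman test with replicated blocks
# ---------------------------------------------------------------------------

@dataclass
class FriedmanTable:
    """ANOVA-style decomposition of within-block ranks.

    ``rows`` holds (source, SS, df, MS) for Columns / Interaction /
    Error / Total in display order. The block (dataset) source carries
    df d-1 but zero SS by construction (within-block ranking equalises
    block means), so it is folded into the accounting without a printed
    row - its df is still subtracted from the Error df.
    """

    ss_columns: float
    ss_interaction: float
    ss_error: float
    ss_total: float
    df_columns: int
    df_interaction: int
    df_error: int
    df_total: int
    chi_sq: float
    p_value: float
    avg_ranks: np.ndarray = field(default=None)
    n_blocks_effective: int = 0

    @property
    def rows(self) -> list[tuple]:
        def ms(ss, df):
            return ss / df if df > 0 else float("nan")

        return [
            ("Columns", self.ss_columns, self.df_columns, ms(self.ss_columns, self.df_columns)),
            ("Interaction", self.ss_interaction, self.df_interaction,
             ms(self.ss_interaction, self.df_interaction)),
            ("Error", self.ss_error, self.df_error, ms(self.ss_error, self.df_error)),
            ("Total", self.ss_total, self.df_total, float("nan")),
        ]

    def to_dict(self) -> dict:
        return {
            "rows": [
                {"source": s, "ss": ss, "df": df, "ms": ms}
                for s, ss, df, ms in self.rows
            ],
            "chi_sq": self.chi_sq,
            "p_value": self.p_value,
            "avg_ranks": list(self.avg_ranks),
        }


def friedman_test(scores: np.ndarray, d: int, r: int) -> FriedmanTable:
    """Rank-based comparison of k columns over d blocks of r replicate rows.

    ``scores`` is (d*r, k); consecutive groups of r rows form one
    block. All r*k values of a block are ranked jointly (average ranks
    for ties). The chi-square statistic is the Columns SS divided by
    the pooled within-block rank variance S_total / (d * (r*k - 1)),
    which reduces to the classic tie-corrected Friedman statistic when
    r = 1; p comes from the chi-square distribution with k-1 df.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ContractError("scores must be a 2-D matrix")
    n, k = X.shape
    if k < 2 or d < 1 or r < 1 or n != d * r:
        raise ContractError(f"shape {X.shape} incompatible with d={d}, r={r}")
    if not np.isfinite(X).all():
        raise ContractError("scores must not contain missing values")

    R = np.empty_like(X)
    for b in range(d):
        block = X[b * r:(b + 1) * r]
        R[b * r:(b + 1) * r] = rankdata(block, axis=None).reshape(r, k)

    grand = R.mean()
    col_means = R.mean(axis=0)
    block_means = R.reshape(d, r * k).mean(axis=1)
    cell_means = R.reshape(d, r, k).mean(axis=1)          # (d, k)

    ss_total = float(((R - grand) ** 2).sum())
    ss_col = float(n * ((col_means - grand) ** 2).sum())
    ss_blocks = float(r * k * ((block_means - grand) ** 2).sum())  # 0 up to fp error
    ss_inter = float(
        r * ((cell_means - col_means[None, :] - block_means[:, None] + grand) ** 2).sum()
    )
    ss_error = ss_total - ss_blocks - ss_col - ss_inter

    df_col = k - 1
    df_blocks = d - 1
    df_inter = (k - 1) * (d - 1)
    df_total = n * k - 1
    df_error = df_total - df_blocks - df_col - df_inter

    denom = ss_total / (d * (r * k - 1))
    chi_sq = 0.0 if denom == 0.0 else ss_col / denom
    p = 1.0 if denom == 0.0 else float(chi2.sf(chi_sq, df_col))
    return FriedmanTable(
        ss_columns=ss_col,
        ss_interaction=ss_inter,
        ss_error=ss_error,
        ss_total=ss_total,
        df_columns=df_col,
        df_interaction=df_inter,
        df_error=df_error,
        df_total=df_total,
        chi_sq=float(chi_sq),
        p_value=p,
        avg_ranks=col_means,
        n_blocks_effective=n,
    )


# ---------------------------------------------------------------------------
# Nemenyi post-hoc test
# ---------------------------------------------------------------------------

#: Critical values q_alpha(k) for the Nemenyi test (Studentized range at
#: infinite df divided by sqrt(2)), k = 2..10.
NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass
class NemenyiResult:
    avg_ranks: np.ndarray
    critical_distance: float
    significant: np.ndarray   # (k, k) bool
    alpha: float

    def to_dict(self) -> dict:
        return {
            "avg_ranks": list(self.avg_ranks),
            "critical_distance": self.critical_distance,
            "significant": self.significant.tolist(),
            "alpha": self.alpha,
        }


def nemenyi(avg_ranks: np.ndarray, n_blocks: int, alpha: float = 0.05) -> NemenyiResult:
    """Pairwise comparisons: ranks differ when |r_i - r_j| >= CD.

    CD = q_alpha(k) * sqrt(k (k + 1) / (6 n_blocks)).
    """
    ranks = np.asarray(avg_ranks, dtype=float)
    k = ranks.shape[0]
    if alpha not in NEMENYI_Q:
        raise ConfigError(
            f"alpha={alpha} unsupported; supported: {sorted(NEMENYI_Q)}"
        )
    if k not in NEMENYI_Q[alpha]:
        raise ConfigError(f"no critical value tabulated for k={k}")
    cd = NEMENYI_Q[alpha][k] * np.sqrt(k * (k + 1) / (6.0 * n_blocks))
    diff = np.abs(ranks[:, None] - ranks[None, :])
    sig = diff >= cd
    np.fill_diagonal(sig, False)
    return NemenyiResult(avg_ranks=ranks, critical_distance=float(cd),
                         significant=sig, alpha=alpha)


# ---------------------------------------------------------------------------
# Cross-algorithm report
# ---------------------------------------------------------------------------

def fold_metric_matrix(
    fold_metrics: dict[str, dict[str, list[MetricSet]]],
    metric: str,
    algorithms: list[str] | None = None,
) -> tuple[np.ndarray, list[str], int, int]:
    """Assemble the (datasets*folds, algorithms) matrix for one metric.

    ``fold_metrics`` maps dataset -> algorithm -> per-fold MetricSets.
    Fold rows where any algorithm's metric is undefined are dropped with
    a warning; if any row is dropped the block structure collapses to
    one row per block (pure Friedman).
    """
    if metric not in METRIC_NAMES:
        raise ConfigError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    datasets = sorted(fold_metrics)
    if algorithms is None:
        algorithms = sorted(fold_metrics[datasets[0]])
    rows = []
    dropped = 0
    n_folds = None
    for ds in datasets:
        per_alg = fold_metrics[ds]
        folds = {len(per_alg[a]) for a in algorithms}
        if len(folds) != 1:
            raise ContractError(f"algorithms disagree on fold count in dataset {ds!r}")
        r = folds.pop()
        if n_folds is None:
            n_folds = r
        elif n_folds != r:
            raise ContractError("datasets disagree on fold count")
        for f in range(r):
            vals = [per_alg[a][f][metric] for a in algorithms]
            if any(v is None for v in vals):
                dropped += 1
                continue
            rows.append(vals)
    if dropped:
        log.warning(
            "%d fold row(s) dropped: undefined %s metric; comparison falls "
            "back to unreplicated blocks", dropped, metric,
        )
    X = np.asarray(rows, dtype=float)
    if dropped:
        d, r = X.shape[0], 1
    else:
        d, r = len(datasets), n_folds
    return X, algorithms, d, r


def compare_algorithms(
    fold_metrics: dict[str, dict[str, list[MetricSet]]],
    metric: str = "f1",
    alpha: float = 0.05,
) -> dict:
    """Friedman test on per-fold metrics, Nemenyi post-hoc when p < alpha.

    Returns a JSON-serializable report with mean (SD) summaries per
    dataset/algorithm, the rank table, and pairwise significance.
    """
    X, algorithms, d, r = fold_metric_matrix(fold_metrics, metric)
    table = friedman_test(X, d, r)
    report = {
        "metric": metric,
        "algorithms": algorithms,
        "friedman": table.to_dict(),
        "summary": summarize_folds(fold_metrics, algorithms),
        "nemenyi": None,
    }
    if table.p_value < alpha:
        # average ranks on the 1..k scale, higher metric = better = lower rank
        per_row = np.apply_along_axis(lambda v: rankdata(-v), 1, X)
        avg_ranks = per_row.mean(axis=0)
        report["nemenyi"] = nemenyi(avg_ranks, X.shape[0], alpha).to_dict()
    return report


def summarize_folds(
    fold_metrics: dict[str, dict[str, list[MetricSet]]],
    algorithms: list[str],
) -> dict:
    """Per-dataset mean (SD) strings for every metric, Table-style."""
    out: dict = {}
    for ds, per_alg in fold_metrics.items():
        out[ds] = {}
        for alg in algorithms:
            out[ds][alg] = {}
            for m in METRIC_NAMES:
                vals = [ms[m] for ms in per_alg[alg] if ms[m] is not None]
                if vals:
                    mean = float(np.mean(vals))
                    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                    out[ds][alg][m] = f"{mean:.4f} ({sd:.4f})"
                else:
                    out[ds][alg][m] = "undefined"
    return out


def report_markdown(report: dict) -> str:
    """Render a comparison report as Markdown tables."""
    lines = [f"## Comparison on {report['metric']}", ""]
    lines.append("| Source | SS | df | MS |")
    lines.append("|---|---|---|---|")
    for row in report["friedman"]["rows"]:
        ms = "" if row["ms"] != row["ms"] else f"{row['ms']:.2f}"  # NaN check
        lines.append(f"| {row['source']} | {row['ss']:.2f} | {row['df']} | {ms} |")
    lines.append("")
    lines.append(
        f"Chi-sq = {report['friedman']['chi_sq']:.2f}, "
        f"p = {report['friedman']['p_value']:.4g}"
    )
    if report["nemenyi"]:
        nm = report["nemenyi"]
        lines.append("")
        lines.append(f"Nemenyi CD = {nm['critical_distance']:.4f} (alpha={nm['alpha']})")
        lines.append("| Algorithm | Avg rank |")
        lines.append("|---|---|")
        for alg, rk in zip(report["algorithms"], nm["avg_ranks"]):
            lines.append(f"| {alg} | {rk:.3f} |")
    return "\n".join(lines)
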