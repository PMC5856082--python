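import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from fallbench.errors import ConfigError, ContractError
from fallbench.evaluation import (
    ConfusionMatrix,
    MetricSet,
    compare_algorithms,
    fold_metric_matrix,
    friedman_test,
    metrics,
    nemenyi,
    report_markdown,
    summarize_folds,
)


def friedman_oracle_chisq(X):
    """Textbook tie-corrected Friedman statistic, per-row ranking.

    chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum r_ij^2 - n k (k+1)^2 / 4)
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    R = np.vstack([rankdata(row) for row in X])
    Rj = R.sum(axis=0)
    A = float((R**2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    if A == C:
        return 0.0
    return float((k - 1) * ((Rj - n * (k + 1) / 2.0) ** 2).sum() / (A - C))


class TestMetrics:
    def test_derived_example(self):
        m = metrics(ConfusionMatrix(tp=9, fn=1, tn=90, fp=10))
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.9)
        assert m.precision == pytest.approx(9 / 19)
        assert m.f1 == pytest.approx(2 * (9 / 19) * 0.9 / (9 / 19 + 0.9))

    def test_perfect_detector(self):
        m = metrics(ConfusionMatrix(tp=5, tn=7, fp=0, fn=0))
        assert (m.sensitivity, m.specificity, m.precision, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominators_undefined(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=2))
        assert m.precision is None
        assert m.sensitivity == 0.0
        assert m.f1 is None

    def test_all_zero_matrix(self):
        m = metrics(ConfusionMatrix())
        assert all(v is None for v in m.to_dict().values())

    def test_negative_counts_rejected(self):
        with pytest.raises(ContractError):
            ConfusionMatrix(tp=-1)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(deadline=None, max_examples=200)
    def test_f1_harmonic_identity(self, tp, tn, fp, fn):
        m = metrics(ConfusionMatrix(tp, tn, fp, fn))
        if m.f1 is not None:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.sensitivity / (m.precision + m.sensitivity), abs=1e-12
            )


class TestFriedman:
    def test_identical_columns_chisq_zero(self, rng):
        col = rng.normal(size=12)
        X = np.tile(col[:, None], (1, 4))
        t = friedman_test(X, d=3, r=4)
        assert t.chi_sq == 0.0
        assert t.p_value == 1.0

    def test_closed_form_90(self, rng):
        X = np.sort(rng.normal(size=(30, 4)), axis=1)
        t = friedman_test(X, d=30, r=1)
        assert t.chi_sq == pytest.approx(90.0, abs=1e-9)

    def test_df_structure_paper_layout(self, rng):
        X = rng.normal(size=(30, 4))
        t = friedman_test(X, d=3, r=10)
        assert (t.df_columns, t.df_interaction, t.df_error, t.df_total) == (3, 6, 108, 119)

    @pytest.mark.parametrize("k,d,r", [(2, 2, 3), (3, 4, 1), (5, 2, 4), (4, 3, 10)])
    def test_df_structure_sweep(self, k, d, r, rng):
        X = rng.normal(size=(d * r, k))
        t = friedman_test(X, d=d, r=r)
        assert t.df_columns == k - 1
        assert t.df_interaction == (k - 1) * (d - 1)
        assert t.df_total == d * r * k - 1
        assert t.df_error == t.df_total - (d - 1) - t.df_columns - t.df_interaction

    def test_ss_additive(self, rng):
        X = rng.integers(0, 4, size=(20, 5)).astype(float)  # ties on purpose
        t = friedman_test(X, d=4, r=5)
        assert t.ss_columns + t.ss_interaction + t.ss_error == pytest.approx(
            t.ss_total, abs=1e-9
        )

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            k = int(rng.integers(2, 6))
            X = rng.integers(0, 5, size=(n, k)).astype(float)
            t = friedman_test(X, d=n, r=1)
            assert t.chi_sq == pytest.approx(friedman_oracle_chisq(X), abs=1e-9)

    def test_column_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        perm = [2, 0, 3, 1]
        t1 = friedman_test(X, d=3, r=10)
        t2 = friedman_test(X[:, perm], d=3, r=10)
        assert t2.chi_sq == pytest.approx(t1.chi_sq, abs=1e-9)
        np.testing.assert_allclose(t2.avg_ranks, t1.avg_ranks[perm], atol=1e-9)

    def test_shape_validation(self, rng):
        with pytest.raises(ContractError):
            friedman_test(rng.normal(size=(10, 3)), d=3, r=4)
        with pytest.raises(ContractError):
            friedman_test(np.full((4, 2), np.nan), d=4, r=1)


class TestNemenyi:
    def test_critical_distance_value(self):
        res = nemenyi(np.array([1.0, 2.0, 3.0, 4.0]), n_blocks=30, alpha=0.05)
        assert res.critical_distance == pytest.approx(2.569 * np.sqrt(20 / 180), abs=1e-4)

    def test_equal_ranks_not_significant(self):
        res = nemenyi(np.array([2.5, 2.5]), n_blocks=30, alpha=0.05)
        assert not res.significant.any()

    def test_wide_gap_significant(self):
        res = nemenyi(np.array([1.0, 4.0]), n_blocks=30, alpha=0.05)
        assert res.significant[0, 1]

    def test_cd_monotonic(self):
        cd_small_n = nemenyi(np.zeros(4), n_blocks=10, alpha=0.05).critical_distance
        cd_big_n = nemenyi(np.zeros(4), n_blocks=100, alpha=0.05).critical_distance
        assert cd_big_n < cd_small_n
        cd_k5 = nemenyi(np.zeros(5), n_blocks=30, alpha=0.05).critical_distance
        cd_k4 = nemenyi(np.zeros(4), n_blocks=30, alpha=0.05).critical_distance
        assert cd_k5 > cd_k4

    def test_unsupported_alpha(self):
        with pytest.raises(ConfigError, match="0.05"):
            nemenyi(np.zeros(4), n_blocks=30, alpha=0.01)


def _fold_metrics(values):
    """dataset -> alg -> list of MetricSets with the given f1 values."""
    out = {}
    for ds, algs in values.items():
        out[ds] = {
            alg: [MetricSet(v, v, v, v) for v in vals] for alg, vals in algs.items()
        }
    return out


class TestCompare:
    def test_dominant_algorithm_flagged(self, rng):
        values = {}
        for ds in ("a", "b", "c"):
            good = list(0.9 + 0.01 * rng.random(10))
            mid = list(0.6 + 0.01 * rng.random(10))
            bad = list(0.2 + 0.01 * rng.random(10))
            worse = list(0.05 + 0.01 * rng.random(10))
            values[ds] = {"alg_g": good, "alg_m": mid, "alg_b": bad, "alg_w": worse}
        report = compare_algorithms(_fold_metrics(values), metric="f1", alpha=0.05)
        assert report["friedman"]["p_value"] < 0.05
        nm = report["nemenyi"]
        ranks = dict(zip(report["algorithms"], nm["avg_ranks"]))
        assert ranks["alg_g"] == min(ranks.values())  # rank 1 = best
        i = report["algorithms"].index("alg_g")
        j = report["algorithms"].index("alg_w")
        assert nm["significant"][i][j]

    def test_identical_algorithms_p1(self):
        vals = {"a": {"x": [0.5] * 10, "y": [0.5] * 10}}
        report = compare_algorithms(_fold_metrics(vals), metric="f1")
        assert report["friedman"]["p_value"] == 1.0
        assert report["nemenyi"] is None

    def test_summary_formatting(self):
        vals = {"a": {"x": [0.9, 0.92], "y": [0.5, 0.6]}}
        summary = summarize_folds(_fold_metrics(vals), ["x", "y"])
        mean_sd = summary["a"]["x"]["f1"]
        assert mean_sd == "0.9100 (0.0141)"

    def test_undefined_folds_dropped(self, caplog):
        fm = _fold_metrics({"a": {"x": [0.5] * 10, "y": [0.4] * 10}})
        fm["a"]["x"][3] = MetricSet(None, None, None, None)
        with caplog.at_level("WARNING"):
            X, algs, d, r = fold_metric_matrix(fm, "f1")
        assert X.shape == (9, 2)
        assert (d, r) == (9, 1)

    def test_mismatched_folds_error(self):
        fm = _fold_metrics({"a": {"x": [0.5] * 10, "y": [0.4] * 9}})
        with pytest.raises(ContractError):
            fold_metric_matrix(fm, "f1")

    def test_markdown_renders(self, rng):
        vals = {"a": {"x": list(rng.random(10)), "y": list(rng.random(10))}}
        text = report_markdown(compare_algorithms(_fold_metrics(vals)))
        assert "| Source |" in text
        assert "Chi-sq" in text
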