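"""Repeated-split benchmark harness and Sensitivity/Specificity/BA metrics."""

import numpy as np
import pandas as pd
import pytest

import gnetox.evaluation as ev
from gnetox.evaluation import (
    BenchmarkConfig,
    aggregate,
    compute_metrics,
    make_splits,
    run_benchmark,
)


class TestMakeSplits:
    def test_union_and_disjointness(self):
        ss = make_splits(37, R=8, test_frac=0.3, seed=0)
        for tr, te in ss:
            assert len(np.intersect1d(tr, te)) == 0
            assert sorted(np.concatenate([tr, te]).tolist()) == list(range(37))

    def test_deterministic_given_seed(self):
        a = make_splits(30, R=5, seed=3)
        b = make_splits(30, R=5, seed=3)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)

    def test_test_size_404_quarter_gives_101(self):
        y = np.zeros(404, int)
        y[:60] = 1
        ss = make_splits(404, R=50, test_frac=0.25, seed=1, stratify_on=y)
        assert all(len(te) == 101 for _, te in ss)

    def test_stratified_keeps_both_classes(self):
        y = np.zeros(40, int)
        y[:4] = 1
        ss = make_splits(40, R=10, test_frac=0.25, seed=2, stratify_on=y)
        for tr, te in ss:
            assert y[tr].sum() >= 1 and y[te].sum() >= 1

    def test_infeasible_stratification_raises_with_counts(self):
        y = np.zeros(20, int)
        y[0] = 1
        with pytest.raises(ValueError, match="class counts"):
            make_splits(20, R=3, stratify_on=y)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_splits(3)


class TestComputeMetrics:
    def test_formula_example(self):
        # TP=3, FN=1, TN=5, FP=5
        y_true = [1] * 4 + [0] * 10
        y_pred = [1, 1, 1, 0] + [1] * 5 + [0] * 5
        m = compute_metrics(y_true, y_pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 5, 5)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.5)
        assert m.balanced_accuracy == pytest.approx(0.625)

    def test_perfect_prediction(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert m.balanced_accuracy == 1.0

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            m = compute_metrics(y, p)
            tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
            for yi, pi in zip(y, p):
                key = ("t" if yi == pi else "f") + ("p" if pi == 1 else "n")
                tally[key] += 1
            assert (m.tp, m.fp, m.tn, m.fn) == (
                tally["tp"], tally["fp"], tally["tn"], tally["fn"]
            )
            assert m.tp + m.fp + m.tn + m.fn == 50

    def test_undefined_metric_is_nan_not_zero(self):
        m = compute_metrics([0, 0, 0], [0, 1, 0])
        assert np.isnan(m.sensitivity)
        assert np.isnan(m.balanced_accuracy)
        assert m.specificity == pytest.approx(2 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])


class TestBenchmark:
    def test_majority_baseline_on_unbalanced_assay(self, small_table):
        table, _ = small_table
        res = run_benchmark(table, methods=("majority",), R=3, seed=5,
                            conditions=("unbalanced",))
        assert np.allclose(res["sensitivity"], 0.0)
        assert np.allclose(res["specificity"], 1.0)
        assert np.allclose(res["balanced_accuracy"], 0.5)

    def test_aggregate_equals_arithmetic_mean(self, small_table):
        table, _ = small_table
        res = run_benchmark(table, methods=("xgboost",), R=4, seed=6,
                            conditions=("unbalanced",))
        agg = aggregate(res)
        for _, row in agg.iterrows():
            grp = res[(res.assay == row["assay"])
                      & (res.method == row["method"])
                      & (res.condition == row["condition"])]
            assert row["balanced_accuracy_mean"] == pytest.approx(
                grp["balanced_accuracy"].mean()
            )

    def test_test_partitions_identical_across_conditions(self, small_table,
                                                         monkeypatch):
        # paired-comparison contract: the augmented condition must score
        # on byte-identical test sets
        table, _ = small_table
        seen = {}
        orig = ev._fit_predict

        def spy(method, Xtr, ytr, Xte, seed, cfg):
            seen.setdefault(seed, []).append(Xte.tobytes())
            return orig(method, Xtr, ytr, Xte, seed, cfg)

        monkeypatch.setattr(ev, "_fit_predict", spy)
        run_benchmark(table, methods=("majority",), R=3, seed=7)
        assert seen
        for blobs in seen.values():
            assert len(blobs) == 2  # unbalanced + augmented
            assert blobs[0] == blobs[1]

    def test_training_failure_recorded_not_fatal(self, small_table):
        table, _ = small_table
        cfg = BenchmarkConfig(mlrnn={"n_trials": 1, "ridge_grid": []})
        res = run_benchmark(table, methods=("mlrnn", "majority"), R=2, seed=8,
                            conditions=("unbalanced",), config=cfg)
        failed = res[res.method == "mlrnn"]
        assert (failed["error"] != "").all()
        assert failed["balanced_accuracy"].isna().all()
        ok = res[res.method == "majority"]
        assert (ok["error"] == "").all()
        agg = aggregate(res)
        excl = agg[agg.method == "mlrnn"]["n_excluded"]
        assert (excl == 2).all()

    def test_unknown_method_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ValueError, match="no adapter"):
            run_benchmark(table, methods=("svm",), R=2, seed=9)

    def test_empty_methods_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ValueError):
            run_benchmark(table, methods=(), R=2, seed=9)

    def test_reproducible_from_seed(self, small_table):
        table, _ = small_table
        a = run_benchmark(table, methods=("xgboost",), R=2, seed=10,
                          conditions=("unbalanced",))
        b = run_benchmark(table, methods=("xgboost",), R=2, seed=10,
                          conditions=("unbalanced",))
        pd.testing.assert_frame_equal(a, b)
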