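"""Exclusion curves, cutoff rules, and classification metrics."""

import io

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, f1_score

from mcishapley import (
    ConfusionCounts,
    ModelSpec,
    accuracy,
    confusion_counts,
    exclusion_curve,
    f1,
    no_information_rate,
    rank_and_exclude,
    select_cutoff,
    train_and_eval,
    zero_cutoff,
)


class TestMetrics:
    def test_hand_arithmetic(self):
        c = ConfusionCounts(tp=2, fp=1, fn=1, tn=2)
        assert accuracy(c) == pytest.approx(4 / 6)
        assert f1(c) == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        c = ConfusionCounts(tp=5, fp=0, fn=0, tn=5)
        assert accuracy(c) == 1.0
        assert f1(c) == 1.0

    def test_no_true_positives_gives_zero_f1(self):
        c = ConfusionCounts(tp=0, fp=2, fn=3, tn=5)
        assert f1(c) == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(["sMCI", "pMCI"], size=200)
        y_pred = rng.choice(["sMCI", "pMCI"], size=200)
        c = confusion_counts(y_true, y_pred)
        assert accuracy(c) == pytest.approx(accuracy_score(y_true, y_pred))
        assert f1(c) == pytest.approx(
            f1_score(y_true, y_pred, pos_label="pMCI")
        )

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((80, 64), 80 / 144),   # internal test-set composition
            ((16, 12), 16 / 28),    # external cohort composition
            ((50, 50), 0.5),
        ],
    )
    def test_no_information_rate(self, counts, expected):
        labels = ["sMCI"] * counts[0] + ["pMCI"] * counts[1]
        assert no_information_rate(labels) == pytest.approx(expected)

    def test_majority_predictor_accuracy_equals_nir(self):
        labels = np.array(["sMCI"] * 70 + ["pMCI"] * 30)
        pred = np.array(["sMCI"] * 100)
        c = confusion_counts(labels, pred)
        assert accuracy(c) == no_information_rate(labels)


class TestRanking:
    def test_smallest_values_excluded_first(self):
        values = pd.Series([-0.1, 0.2, -0.05, 0.3], index=[1, 2, 3, 4])
        assert rank_and_exclude(values, 2) == [2, 4]

    def test_k_zero_is_identity(self):
        values = pd.Series([0.5, -0.5], index=["a", "b"])
        assert rank_and_exclude(values, 0) == ["a", "b"]

    def test_ties_break_by_ascending_subject_id(self):
        values = pd.Series([0.1, 0.1, 0.1], index=["c", "a", "b"])
        assert rank_and_exclude(values, 1) == ["c", "b"]  # "a" excluded first

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(size=40), index=range(40))
        for k in (0, 5, 17, 39):
            expected = set(values.sort_values(kind="mergesort").index[k:])
            assert set(rank_and_exclude(values, k)) == expected

    def test_nestedness_of_retained_sets(self):
        rng = np.random.default_rng(2)
        values = pd.Series(rng.normal(size=30), index=range(30))
        bigger = set(rank_and_exclude(values, 20))
        smaller = set(rank_and_exclude(values, 5))
        assert bigger <= smaller

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rank_and_exclude(pd.Series([1.0, 2.0]), 2)

    def test_zero_cutoff_counts_strictly_negative(self):
        assert zero_cutoff([-0.1, 0.0, 0.2]) == 1
        assert zero_cutoff([0.3, 0.1]) == 0
        rng = np.random.default_rng(3)
        v = rng.normal(size=100)
        assert zero_cutoff(v) == int((v < 0).sum())


class TestCutoffSelection:
    def _curve(self, pairs, eval_set="valid"):
        return pd.DataFrame(
            [
                {"strategy": "shapley", "eval_set": eval_set, "n_excluded": k,
                 "acc_mean": a, "f1_mean": a, "acc_sd": 0.0, "f1_sd": 0.0}
                for k, a in pairs
            ]
        )

    def test_argmax_of_mean_accuracy(self):
        curve = self._curve([(0, 0.60), (50, 0.66), (100, 0.64)])
        assert select_cutoff(curve).n_excluded == 50

    def test_tie_breaks_toward_fewer_exclusions(self):
        curve = self._curve([(0, 0.66), (50, 0.66)])
        assert select_cutoff(curve).n_excluded == 0

    def test_max_test_flagged_optimistic(self):
        curve = self._curve([(0, 0.6), (10, 0.7)], eval_set="test")
        res = select_cutoff(curve, "max-test")
        assert res.optimistic and res.n_excluded == 10

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(4)
        grid = list(range(0, 200, 10))
        accs = rng.random(len(grid))
        curve = self._curve(list(zip(grid, accs)))
        expected = grid[int(np.argmax(accs))]
        assert select_cutoff(curve).n_excluded == expected


def _blobs(n=60, distance=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        np.vstack(
            [rng.normal(0, 1, size=(n // 2, 3)),
             rng.normal(distance, 1, size=(n // 2, 3))]
        ),
        columns=list("abc"),
        index=[f"S{i}" for i in range(n)],
    )
    y = pd.Series(["sMCI"] * (n // 2) + ["pMCI"] * (n // 2), index=X.index)
    return X, y


class TestTrainAndEval:
    def test_separable_blobs_reach_perfect_accuracy(self):
        X, y = _blobs()
        out = train_and_eval(X, y, X, y, ModelSpec("random-forest"), range(10))
        assert out["acc_mean"] == 1.0
        assert out["acc_sd"] == 0.0

    def test_same_seeds_give_identical_aggregates(self):
        X, y = _blobs(distance=1.0)
        spec = ModelSpec("random-forest")
        a = train_and_eval(X, y, X, y, spec, [3, 4, 5])
        b = train_and_eval(X, y, X, y, spec, [3, 4, 5])
        assert a == b

    def test_permuted_labels_score_near_no_information_rate(self):
        rng = np.random.default_rng(5)
        X, y = _blobs(n=400, distance=0.0, seed=6)  # no signal at all
        y = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        Xe, ye = _blobs(n=200, distance=0.0, seed=7)
        out = train_and_eval(X, y, Xe, ye, ModelSpec("random-forest"), range(10))
        nir = no_information_rate(ye)
        assert abs(out["acc_mean"] - nir) < max(3 * out["acc_sd"], 0.1)

    def test_single_class_training_subset_rejected(self):
        X, y = _blobs()
        with pytest.raises(ValueError, match="single class"):
            train_and_eval(X, y[y == "sMCI"].reindex(X.index[:30]),
                           X, y, ModelSpec("random-forest"), [0])

    def test_xgboost_family_supported(self):
        X, y = _blobs()
        out = train_and_eval(X, y, X, y, ModelSpec("xgboost"), [0, 1])
        assert out["acc_mean"] == 1.0


class TestExclusionCurve:
    def test_grid_zero_equals_base_model_for_every_strategy(self):
        X, y = _blobs(n=40, distance=2.0)
        rng = np.random.default_rng(8)
        values = pd.Series(rng.normal(size=len(y)), index=y.index)
        spec = ModelSpec("random-forest")
        eval_sets = {"test": (X, y)}
        ranked = exclusion_curve("shapley", X, y, eval_sets, spec, grid=[0],
                                 values=values, repetition_seeds=[0, 1, 2])
        rand = exclusion_curve("random", X, y, eval_sets, spec, grid=[0],
                               repetition_seeds=[0, 1, 2])
        assert ranked["acc_mean"].iloc[0] == rand["acc_mean"].iloc[0]

    def test_curve_rows_round_trip_through_csv(self):
        X, y = _blobs(n=40, distance=2.0)
        values = pd.Series(np.arange(len(y), dtype=float), index=y.index)
        curve = exclusion_curve(
            "shapley", X, y, {"test": (X, y)}, ModelSpec("random-forest"),
            grid=[0, 10], values=values, repetition_seeds=[0, 1],
        )
        buf = io.StringIO()
        curve.to_csv(buf, index=False)
        buf.seek(0)
        back = pd.read_csv(buf)
        pd.testing.assert_frame_equal(curve, back)

    def test_mean_invariant_to_repetition_seed_order(self):
        X, y = _blobs(n=40, distance=1.0)
        values = pd.Series(np.arange(len(y), dtype=float), index=y.index)
        spec = ModelSpec("random-forest")
        a = exclusion_curve("shapley", X, y, {"t": (X, y)}, spec, grid=[10],
                            values=values, repetition_seeds=[0, 1, 2])
        b = exclusion_curve("shapley", X, y, {"t": (X, y)}, spec, grid=[10],
                            values=values, repetition_seeds=[2, 0, 1])
        assert a["acc_mean"].iloc[0] == pytest.approx(b["acc_mean"].iloc[0])

    def test_degenerate_gridpoint_recorded_as_missing(self):
        X, y = _blobs(n=20, distance=2.0)
        # values rank one class uniformly lowest -> large k leaves one class
        values = pd.Series(
            np.where(y == "sMCI", -1.0, 1.0), index=y.index
        ) + np.arange(len(y)) * 1e-6
        curve = exclusion_curve(
            "shapley", X, y, {"t": (X, y)}, ModelSpec("random-forest"),
            grid=[0, 15], values=values, repetition_seeds=[0],
        )
        assert np.isnan(curve.loc[curve["n_excluded"] == 15, "acc_mean"]).all()
        assert np.isfinite(curve.loc[curve["n_excluded"] == 0, "acc_mean"]).all()

    def test_ranked_strategy_requires_values(self):
        X, y = _blobs(n=20)
        with pytest.raises(ValueError, match="values"):
            exclusion_curve("shapley", X, y, {"t": (X, y)},
                            ModelSpec("random-forest"), grid=[0])
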