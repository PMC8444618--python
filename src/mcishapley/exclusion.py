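"""Exclusion-curve experiments: value-ranked subject removal and evaluation.

Training subjects with the smallest data values are successively excluded
and a fresh classifier ensemble (default ten seeds) is trained and
evaluated at each exclusion count, yielding mean +- sd accuracy and
F1-score curves per evaluation set.  Three cutoff rules summarise a curve:
``zero-cutoff`` removes all subjects with negative values, ``max-valid``
picks the exclusion count maximising mean validation accuracy, and
``max-test`` does the same on the test set (an optimistic bound, flagged
as such).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .valuation import ModelSpec

__all__ = [
    "ConfusionCounts",
    "CutoffResult",
    "confusion_counts",
    "accuracy",
    "f1",
    "no_information_rate",
    "rank_and_exclude",
    "zero_cutoff",
    "train_and_eval",
    "exclusion_curve",
    "select_cutoff",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 contingency counts; the positive class is pMCI."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(y_true, y_pred, positive=schema.POSITIVE_CLASS) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("empty contingency table")
    return (c.tp + c.tn) / c.total


def f1(c: ConfusionCounts) -> float:
    """F1 = TP / (TP + (FP + FN) / 2); zero when TP = 0 with errors present."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        raise ValueError("F1 undefined: no positives predicted or present")
    return c.tp / denom


def no_information_rate(labels) -> float:
    """Majority-class proportion: the accuracy of always predicting it."""
    labels = pd.Series(labels)
    if len(labels) == 0:
        raise ValueError("empty label set")
    return float(labels.value_counts().iloc[0] / len(labels))


# ---------------------------------------------------------------------------
# Ranking and cutoffs
# ---------------------------------------------------------------------------


def rank_and_exclude(values: pd.Series, k: int) -> list:
    """Remove the k subjects with the smallest values; return retained ids.

    Ties break by ascending subject id (stable).  Retained ids keep their
    original order.
    """
    values = pd.Series(values)
    n = len(values)
    if not 0 <= k < n:
        raise ValueError(f"k must satisfy 0 <= k < {n}, got {k}")
    order = values.to_frame("value").reset_index(names="subject_id")
    order = order.sort_values(["value", "subject_id"], kind="mergesort")
    excluded = set(order["subject_id"].iloc[:k])
    return [s for s in values.index if s not in excluded]


def zero_cutoff(values) -> int:
    """Number of subjects with strictly negative values (0 is retained)."""
    return int(np.sum(np.asarray(pd.Series(values)) < 0))


@dataclass
class CutoffResult:
    """Summary of one cutoff rule applied to an exclusion curve."""

    rule: str  # zero-cutoff | max-valid | max-test
    n_excluded: int
    mean_acc: float
    mean_f1: float
    optimistic: bool = False  # max-test is not validated independently


def select_cutoff(curve: pd.DataFrame, rule: str = "max-valid") -> CutoffResult:
    """Argmax of mean accuracy over an exclusion-curve grid.

    Ties break toward the smaller exclusion count.  ``max-test`` results
    carry an ``optimistic`` flag: a cutoff tuned on the test set is not
    validated on independent data.
    """
    if rule not in ("max-valid", "max-test"):
        raise ValueError("rule must be 'max-valid' or 'max-test'")
    curve = curve.dropna(subset=["acc_mean"]).sort_values("n_excluded")
    if len(curve) == 0:
        raise ValueError("empty exclusion curve")
    best = curve.loc[curve["acc_mean"].idxmax()]  # idxmax: first of ties
    return CutoffResult(
        rule=rule,
        n_excluded=int(best["n_excluded"]),
        mean_acc=float(best["acc_mean"]),
        mean_f1=float(best["f1_mean"]),
        optimistic=rule == "max-test",
    )


# ---------------------------------------------------------------------------
# Training and curves
# ---------------------------------------------------------------------------

DEFAULT_N_REPETITIONS = 10


def train_and_eval(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_eval: pd.DataFrame,
    y_eval: pd.Series,
    model_spec: ModelSpec,
    repetition_seeds,
) -> dict[str, float]:
    """Fit one classifier per repetition seed, evaluate on the eval set.

    Returns mean and sd of ACC and F1 over the repetitions.  Raises if the
    training subset contains a single class (can occur at extreme
    exclusion counts).
    """
    y_train = pd.Series(y_train)
    y_eval = pd.Series(y_eval)
    if y_train.nunique() < 2:
        raise ValueError("training subset contains a single class")
    classes = sorted(pd.unique(pd.concat([y_train, y_eval])))
    lookup = {c: k for k, c in enumerate(classes)}
    back = np.array(classes, dtype=object)
    Xt = X_train.to_numpy(dtype=float)
    yt = y_train.map(lookup).to_numpy()
    Xe = X_eval.to_numpy(dtype=float)
    accs, f1s = [], []
    for seed in repetition_seeds:
        model = model_spec.build(seed)
        model.fit(Xt, yt)
        pred = back[np.asarray(model.predict(Xe)).astype(int)]
        c = confusion_counts(y_eval.to_numpy(), pred)
        accs.append(accuracy(c))
        f1s.append(f1(c))
    return {
        "acc_mean": float(np.mean(accs)),
        "acc_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        "f1_mean": float(np.mean(f1s)),
        "f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
    }


def default_grid(n_train: int, step: int = 10) -> list[int]:
    """Exclusion grid {0, step, ...} up to 90% of the training set."""
    return list(range(0, int(0.9 * n_train) + 1, step))


def exclusion_curve(
    strategy: str,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    eval_sets: dict[str, tuple[pd.DataFrame, pd.Series]],
    model_spec: ModelSpec,
    grid=None,
    values: pd.Series | None = None,
    repetition_seeds=None,
    random_seed: int = 0,
) -> pd.DataFrame:
    """Mean +- sd ACC/F1 versus number of lowest-valued subjects excluded.

    ``strategy`` is ``random`` (uniform removal, redrawn per gridpoint and
    repetition seed) or a value-ranked strategy (``loo`` / ``shapley``),
    which requires per-subject ``values``.  One row per (eval set,
    gridpoint); gridpoints whose training subset degenerates to a single
    class are recorded with NaN metrics rather than failing the curve.
    """
    y_train = pd.Series(y_train)
    n = len(y_train)
    if grid is None:
        grid = default_grid(n)
    grid = sorted(set(int(k) for k in grid))
    if grid and (grid[0] < 0 or grid[-1] >= n):
        raise ValueError("grid must satisfy 0 <= k < n_train")
    if repetition_seeds is None:
        repetition_seeds = list(range(DEFAULT_N_REPETITIONS))
    ranked = strategy != "random"
    if ranked and values is None:
        raise ValueError(f"strategy {strategy!r} requires per-subject values")
    rng = np.random.default_rng(random_seed)

    rows = []
    for k in grid:
        if ranked:
            retained = rank_and_exclude(values.loc[y_train.index], k)
            subsets = [retained] * len(repetition_seeds)
        else:
            subsets = [
                list(rng.choice(y_train.index.to_numpy(), size=n - k, replace=False))
                for _ in repetition_seeds
            ]
        for name, (X_eval, y_eval) in eval_sets.items():
            accs, f1s = [], []
            try:
                for seed, subset in zip(repetition_seeds, subsets):
                    res = train_and_eval(
                        X_train.loc[subset],
                        y_train.loc[subset],
                        X_eval,
                        y_eval,
                        model_spec,
                        [seed],
                    )
                    accs.append(res["acc_mean"])
                    f1s.append(res["f1_mean"])
                rows.append(
                    {
                        "strategy": strategy,
                        "eval_set": name,
                        "n_excluded": k,
                        "acc_mean": float(np.mean(accs)),
                        "acc_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                        "f1_mean": float(np.mean(f1s)),
                        "f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
                    }
                )
            except ValueError:
                # degenerate gridpoint (single-class training subset)
                rows.append(
                    {
                        "strategy": strategy,
                        "eval_set": name,
                        "n_excluded": k,
                        "acc_mean": np.nan,
                        "acc_sd": np.nan,
                        "f1_mean": np.nan,
                        "f1_sd": np.nan,
                    }
                )
    return pd.DataFrame(rows)
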