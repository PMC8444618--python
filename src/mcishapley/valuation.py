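"""Per-subject data valuation: leave-one-out, exact Shapley, TMC Shapley.

A training subject's value is its contribution to the validation accuracy
of a base classifier, framed as a cooperative game: the players are the
training subjects, and the payoff V(S) of a coalition S is the validation
accuracy of the classifier fit on S.  Three valuations are provided:

* leave-one-out:  Phi_i = V(D) - V(D \\ {i})  (greedy; violates efficiency),
* exact Shapley by full subset enumeration,
      Phi_i = (1/n) * sum over S subset of D\\{i} of
              [V(S + i) - V(S)] / C(n-1, |S|),
  which satisfies the efficiency axiom  sum_i Phi_i = V(D) - V(empty),
* Truncated Monte Carlo (TMC) Shapley: permutation sampling with
  within-permutation truncation once the running score is within a
  tolerance of V(D), repeated until a windowed convergence criterion or a
  permutation budget is reached; multiple independently seeded runs can be
  averaged.

Performance functions are callables ``v(subject_ids, seed=None) -> score``;
``PerformanceFunction`` provides the standard validation-accuracy game for
scikit-learn / XGBoost base classifiers.  V(empty) is the accuracy of a
majority-class predictor (majority taken over the full training pool).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ModelSpec",
    "PerformanceFunction",
    "ValuationConfig",
    "ValuationResult",
    "loo_valuation",
    "exact_shapley",
    "tmc_shapley",
    "tmc_shapley_averaged",
    "average_iterations",
]


# ---------------------------------------------------------------------------
# Base classifiers
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Base-classifier family with the workflow's fixed hyperparameters.

    Families: ``logistic`` (liblinear, L2, C=1), ``random-forest``
    (50 trees, gini), ``xgboost`` (depth-6 boosted trees, eta 0.3,
    subsample 0.6).  No hyperparameter tuning is performed anywhere in the
    workflow.
    """

    family: str = "logistic"
    seed: int = 0

    _FAMILIES = ("logistic", "random-forest", "xgboost")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from {self._FAMILIES}"
            )

    def build(self, seed: int | None = None):
        seed = self.seed if seed is None else int(seed)
        if self.family == "logistic":
            return LogisticRegression(  # L2 penalty (the default)
                solver="liblinear",
                tol=1e-4,
                C=1.0,
                fit_intercept=True,
                intercept_scaling=1,
                max_iter=5000,
                random_state=seed,
            )
        if self.family == "random-forest":
            return RandomForestClassifier(
                n_estimators=50,
                criterion="gini",
                max_depth=None,
                min_weight_fraction_leaf=0.0,
                max_leaf_nodes=None,
                min_impurity_decrease=0.0,
                bootstrap=True,
                oob_score=False,
                class_weight=None,
                ccp_alpha=0.0,
                max_samples=None,
                random_state=seed,
                n_jobs=1,
            )
        from xgboost import XGBClassifier  # deferred: heavy import

        return XGBClassifier(
            n_estimators=100,
            subsample=0.6,
            objective="binary:logistic",
            booster="gbtree",
            learning_rate=0.3,
            gamma=0,
            max_depth=6,
            min_child_weight=1,
            max_delta_step=0,
            sampling_method="uniform",
            colsample_bytree=1,
            colsample_bylevel=1,
            colsample_bynode=1,
            reg_lambda=1,
            reg_alpha=0,
            scale_pos_weight=1,
            grow_policy="depthwise",
            max_leaves=0,
            max_bin=256,
            num_parallel_tree=1,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )


class PerformanceFunction:
    """Validation-accuracy payoff V(S) for training-subset games.

    ``v(ids, seed=None)`` fits the base classifier on the rows of the
    training pool named by ``ids`` and returns its accuracy on the fixed
    validation set.  The empty coalition scores as a majority-class
    predictor (majority over the full training pool; ties break to the
    lexicographically smallest class).  Single-class coalitions predict
    that class constantly.  Deterministic given (ids, seed).
    """

    def __init__(
        self,
        X_train: pd.DataFrame | np.ndarray,
        y_train,
        X_valid: pd.DataFrame | np.ndarray,
        y_valid,
        model_spec: ModelSpec | None = None,
    ) -> None:
        self.model_spec = model_spec or ModelSpec()
        if isinstance(X_train, pd.DataFrame):
            self.subjects = list(X_train.index)
            self._X = X_train.to_numpy(dtype=float)
        else:
            self._X = np.asarray(X_train, dtype=float)
            self.subjects = list(range(len(self._X)))
        self._pos = {s: i for i, s in enumerate(self.subjects)}
        X_valid = (
            X_valid.to_numpy(dtype=float)
            if isinstance(X_valid, pd.DataFrame)
            else np.asarray(X_valid, dtype=float)
        )
        y_train = np.asarray(pd.Series(y_train).to_numpy())
        y_valid = np.asarray(pd.Series(y_valid).to_numpy())
        self._classes = np.unique(np.concatenate([y_train, y_valid]))
        lookup = {c: k for k, c in enumerate(self._classes)}
        self._y = np.array([lookup[v] for v in y_train])
        self._Xv = X_valid
        self._yv = np.array([lookup[v] for v in y_valid])
        counts = np.bincount(self._y, minlength=len(self._classes))
        self._majority = int(np.argmax(counts))  # ties: smallest class index

    @property
    def empty_score(self) -> float:
        """V(empty): accuracy of the majority-class predictor."""
        return float(np.mean(self._yv == self._majority))

    def __call__(self, ids, seed: int | None = None) -> float:
        idx = [self._pos[s] for s in ids]
        if len(idx) == 0:
            return self.empty_score
        y_sub = self._y[idx]
        present = np.unique(y_sub)
        if len(present) == 1:
            return float(np.mean(self._yv == present[0]))
        model = self.model_spec.build(seed)
        model.fit(self._X[idx], y_sub)
        pred = np.asarray(model.predict(self._Xv))
        return float(np.mean(pred == self._yv))


def _call_v(v, ids, seed):
    """Call a performance function, tolerating seed-less callables."""
    try:
        return float(v(tuple(ids), seed=seed))
    except TypeError:
        return float(v(tuple(ids)))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class ValuationConfig:
    """TMC Shapley settings.

    ``tolerance`` is the within-permutation truncation tolerance on
    |V(D) - running score|; ``err`` the convergence threshold on the
    windowed relative change of the running value estimates, checked every
    ``save_every`` permutations; ``n_iterations`` independently seeded runs
    are averaged.
    """

    n_iterations: int = 4
    tolerance: float = 0.01
    err: float = 0.1
    save_every: int = 100
    max_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.err <= 0:
            raise ValueError("err must be > 0")
        if self.max_permutations < 1:
            raise ValueError("max_permutations must be >= 1")


@dataclass
class ValuationResult:
    """Per-subject data values with convergence diagnostics."""

    subjects: list
    values: np.ndarray
    method: str
    n_permutations: int = 0
    converged: bool | None = None
    seeds: list[int] = field(default_factory=list)
    marginals: np.ndarray | None = None  # (n_permutations, n_subjects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subjects,
                "value": self.values,
                "method": self.method,
                "n_permutations": self.n_permutations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "method": self.method,
            "n_subjects": len(self.subjects),
            "n_permutations": int(self.n_permutations),
            "converged": self.converged,
            "seeds": [int(s) for s in self.seeds],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


# ---------------------------------------------------------------------------
# Valuations
# ---------------------------------------------------------------------------


def loo_valuation(subjects, v) -> ValuationResult:
    """Leave-one-out values Phi_i = V(D) - V(D \\ {i}); n+1 model fits.

    Greedy: the values do not, in general, sum to V(D) - V(empty).
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    full = _call_v(v, subjects, seed=0)
    values = np.empty(len(subjects))
    for i, s in enumerate(subjects):
        rest = [t for t in subjects if t != s]
        values[i] = full - _call_v(v, rest, seed=0)
    return ValuationResult(subjects, values, method="loo")


def exact_shapley(subjects, v, max_n: int = 12) -> ValuationResult:
    """Exact Shapley values by full subset enumeration.

    Evaluates V on all 2^n coalitions and combines marginal contributions
    with the binomial weights of the Shapley formula.  Efficiency
    (sum Phi_i = V(D) - V(empty)) holds to numerical precision.  Refuses
    n > ``max_n``; use TMC Shapley for larger training sets.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds max_n={max_n}: exact enumeration is exponential; "
            "use tmc_shapley for larger sets"
        )
    scores = np.empty(1 << n)
    for mask in range(1 << n):
        ids = [subjects[i] for i in range(n) if mask >> i & 1]
        scores[mask] = _call_v(v, ids, seed=0)
    values = np.zeros(n)
    # 1/(n * C(n-1, s)) weight per coalition size s
    w = np.array([1.0 / (n * math.comb(n - 1, s)) for s in range(n)])
    sizes = np.array([bin(m).count("1") for m in range(1 << n)])
    for i in range(n):
        bit = 1 << i
        without = np.array([m for m in range(1 << n) if not m & bit])
        values[i] = np.sum(
            (scores[without | bit] - scores[without]) * w[sizes[without]]
        )
    return ValuationResult(subjects, values, method="exact-shapley")


def _windowed_error(marginals: np.ndarray, window: int = 100) -> float:
    """Convergence diagnostic: max over the trailing window of the mean
    relative change of the running value estimates."""
    t = len(marginals)
    if t < window:
        return 1.0
    running = np.cumsum(marginals, axis=0) / np.arange(1, t + 1)[:, None]
    last = running[-1:]
    errors = np.mean(
        np.abs(running[-window:] - last) / (np.abs(last) + 1e-12), axis=1
    )
    return float(np.max(errors))


def tmc_shapley(
    subjects, v, config: ValuationConfig | None = None, seed: int | None = None
) -> ValuationResult:
    """One TMC Shapley run (one 'iteration' in the workflow's terms).

    Each permutation adds subjects in random order and records the change
    of validation accuracy as the added subject's marginal contribution;
    once the running score is within ``config.tolerance`` (absolute) of
    V(D), the remaining marginals of that permutation are recorded as 0.
    Base-classifier refits within a permutation reuse one model seed so
    subject-composition effects are isolated from classifier randomness.
    Permutations stop at convergence (windowed criterion, checked every
    ``save_every``) or at ``max_permutations``; the convergence flag
    records which.
    """
    config = config or ValuationConfig()
    subjects = list(subjects)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    v_empty = _call_v(v, [], seed=0)
    v_full = _call_v(v, subjects, seed=0)

    marginals: list[np.ndarray] = []
    converged = False
    while len(marginals) < config.max_permutations:
        perm = rng.permutation(n)
        model_seed = int(rng.integers(0, 2**31 - 1))
        row = np.zeros(n)
        v_prev = v_empty
        for k in range(n):
            if abs(v_full - v_prev) <= config.tolerance:
                break  # truncation: remaining marginals stay 0
            ids = [subjects[j] for j in perm[: k + 1]]
            v_new = _call_v(v, ids, seed=model_seed)
            row[perm[k]] = v_new - v_prev
            v_prev = v_new
        marginals.append(row)
        t = len(marginals)
        if t % config.save_every == 0 and t >= config.save_every:
            if _windowed_error(np.array(marginals)) < config.err:
                converged = True
                break

    m = np.array(marginals)
    return ValuationResult(
        subjects,
        m.mean(axis=0),
        method="tmc-shapley",
        n_permutations=len(m),
        converged=converged,
        seeds=[config.seed if seed is None else seed],
        marginals=m,
    )


def average_iterations(results: list[ValuationResult]) -> ValuationResult:
    """Element-wise mean of per-subject values over equally budgeted runs."""
    if not results:
        raise ValueError("no results to average")
    first = results[0]
    for r in results[1:]:
        if r.subjects != first.subjects:
            raise ValueError("results cover different subject sets")
        if r.method != first.method:
            raise ValueError("results mix valuation methods")
    values = np.mean([r.values for r in results], axis=0)
    marginals = (
        np.vstack([r.marginals for r in results])
        if all(r.marginals is not None for r in results)
        else None
    )
    return ValuationResult(
        first.subjects,
        values,
        method=first.method,
        n_permutations=sum(r.n_permutations for r in results),
        converged=all(bool(r.converged) for r in results)
        if all(r.converged is not None for r in results)
        else None,
        seeds=[s for r in results for s in r.seeds],
        marginals=marginals,
    )


def tmc_shapley_averaged(
    subjects, v, config: ValuationConfig | None = None
) -> ValuationResult:
    """``config.n_iterations`` independently seeded TMC runs, averaged."""
    config = config or ValuationConfig()
    seeds = [config.seed + 1000 * k for k in range(config.n_iterations)]
    runs = [tmc_shapley(subjects, v, config, seed=s) for s in seeds]
    return average_iterations(runs)
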