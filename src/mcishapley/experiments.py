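"""Planted-noise recovery experiments on synthetic cohorts.

These experiments provide the ground-truth check that real cohorts cannot:
a fraction of training labels is flipped on purpose, TMC Shapley values
are computed with a logistic-regression payoff, and we measure (a) how
many flipped subjects fall to the bottom of the value ranking and (b)
whether excluding the lowest-valued subjects recovers classifier accuracy
relative to excluding subjects at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .cohort import etiv_normalize, fit_standardizer
from .features import assemble_model_matrix, mean_threshold_filter, rf_importance_rank
from .synthetic import GeneratorConfig, generate_feature_table, plant_label_noise
from .valuation import (
    ModelSpec,
    PerformanceFunction,
    ValuationConfig,
    tmc_shapley_averaged,
)

__all__ = ["NoiseRecoveryResult", "noise_recovery_experiment", "exclusion_gain"]


@dataclass
class NoiseRecoveryResult:
    """One planted-noise valuation run and its bookkeeping."""

    values: pd.Series                 # per-training-subject TMC Shapley values
    flipped_ids: list                 # training subjects whose label was flipped
    recovered_fraction: float         # flipped subjects in the bottom-30% ranks
    X_train: pd.DataFrame
    y_train: pd.Series                # noisy training labels (as valued)
    y_train_clean: pd.Series
    X_valid: pd.DataFrame
    y_valid: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series
    n_permutations: int
    converged: bool


def _cohort_matrices(config: GeneratorConfig, n_train: int, n_valid: int,
                     n_test: int, seed: int):
    """Generate a cohort and produce standardized, feature-selected matrices."""
    labels_all = pd.Series(
        np.where(
            np.random.default_rng([seed, 11]).random(config.n_subjects)
            < config.class_balance,
            schema.POSITIVE_CLASS,
            schema.CLASSES[0],
        ),
        index=[f"SYN{i:04d}" for i in range(config.n_subjects)],
    )
    features = generate_feature_table(config, labels_all)
    features = etiv_normalize(features)
    rng = np.random.default_rng([seed, 12])
    order = rng.permutation(labels_all.index.to_numpy())
    parts = {
        "train": order[:n_train],
        "valid": order[n_train : n_train + n_valid],
        "test": order[n_train + n_valid : n_train + n_valid + n_test],
    }
    matrix = features.set_index(schema.SUBJECT_ID)
    from .features import encode_clinical

    cols = schema.volumetric_columns() + list(schema.CLINICAL_FEATURES)
    matrix = encode_clinical(matrix)[cols]
    standardizer = fit_standardizer(matrix.loc[parts["train"]])
    matrix = standardizer.transform(matrix)
    importances = rf_importance_rank(
        matrix.loc[parts["train"], schema.volumetric_columns()],
        labels_all.loc[parts["train"]],
        seed=seed,
    )
    selected = mean_threshold_filter(importances)
    X = {
        p: assemble_model_matrix(matrix.loc[ids].reset_index(), selected)
        for p, ids in parts.items()
    }
    y = {p: labels_all.loc[ids] for p, ids in parts.items()}
    return X, y


def noise_recovery_experiment(
    seed: int,
    n_train: int = 200,
    n_valid: int = 100,
    n_test: int = 100,
    noise_fraction: float = 0.2,
    n_iterations: int = 4,
    max_permutations: int = 150,
    bottom_fraction: float = 0.3,
) -> NoiseRecoveryResult:
    """Plant flipped labels, value the training set, measure recovery.

    A synthetic cohort is generated, ``noise_fraction`` of the training
    labels are flipped, and TMC Shapley values are computed with a
    logistic-regression validation-accuracy payoff.  The recovered
    fraction is the share of flipped subjects whose value ranks in the
    bottom ``bottom_fraction`` of the training set.
    """
    config = GeneratorConfig(
        n_subjects=n_train + n_valid + n_test,
        non_mci_baseline_fraction=0.0,
        no_followup_fraction=0.0,
        reversion_fraction=0.0,
        missing_mri_fraction=0.0,
        seed=seed,
    )
    X, y = _cohort_matrices(config, n_train, n_valid, n_test, seed)
    y_clean = y["train"]
    y_noisy, flipped = plant_label_noise(y_clean, noise_fraction, seed)

    perf = PerformanceFunction(
        X["train"], y_noisy, X["valid"], y["valid"], ModelSpec("logistic", seed)
    )
    vconf = ValuationConfig(
        n_iterations=n_iterations, max_permutations=max_permutations, seed=seed
    )
    result = tmc_shapley_averaged(list(X["train"].index), perf, vconf)
    values = pd.Series(result.values, index=result.subjects)

    n_bottom = int(np.ceil(bottom_fraction * n_train))
    order = values.to_frame("value").reset_index(names="sid")
    bottom = set(
        order.sort_values(["value", "sid"], kind="mergesort")["sid"].iloc[:n_bottom]
    )
    recovered = len(bottom & set(flipped)) / max(len(flipped), 1)
    return NoiseRecoveryResult(
        values=values,
        flipped_ids=list(flipped),
        recovered_fraction=recovered,
        X_train=X["train"],
        y_train=y_noisy,
        y_train_clean=y_clean,
        X_valid=X["valid"],
        y_valid=y["valid"],
        X_test=X["test"],
        y_test=y["test"],
        n_permutations=result.n_permutations,
        converged=bool(result.converged),
    )


def exclusion_gain(
    res: NoiseRecoveryResult,
    model_spec: ModelSpec | None = None,
    n_repetitions: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Shapley-ranked versus random exclusion at the planted-noise count.

    Removes k = number-of-flipped-subjects training rows either by lowest
    Shapley value or uniformly at random, trains the final classifier with
    ``n_repetitions`` seeds each way, and reports mean test accuracies.
    """
    from .exclusion import rank_and_exclude, train_and_eval

    model_spec = model_spec or ModelSpec("random-forest", seed)
    k = len(res.flipped_ids)
    rep_seeds = [seed + r for r in range(n_repetitions)]

    retained = rank_and_exclude(res.values, k)
    ranked = train_and_eval(
        res.X_train.loc[retained], res.y_train.loc[retained],
        res.X_test, res.y_test, model_spec, rep_seeds,
    )

    rng = np.random.default_rng(seed)
    accs = []
    for r in rep_seeds:
        keep = rng.choice(res.X_train.index.to_numpy(),
                          size=len(res.X_train) - k, replace=False)
        out = train_and_eval(
            res.X_train.loc[keep], res.y_train.loc[keep],
            res.X_test, res.y_test, model_spec, [r],
        )
        accs.append(out["acc_mean"])
    return {
        "shapley_acc": ranked["acc_mean"],
        "random_acc": float(np.mean(accs)),
        "n_excluded": k,
    }
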