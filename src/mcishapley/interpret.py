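"""Model interpretation with Shapley feature attributions.

A from-scratch Kernel SHAP estimator: binary coalitions of "present"
features are sampled (or fully enumerated when the budget allows), absent
features are imputed from a background set, and the attributions solve the
Shapley-kernel-weighted least-squares problem under the hard constraint
that the base value plus all attributions equals the model output for the
explained instance (local accuracy).  An exact enumeration over all 2^M
coalitions serves as the reference estimator for small M.

Also provides the data views behind the standard displays (summary and
force plots) and the valuation-explanation analysis: per diagnostic group,
a random-forest regressor of per-subject data values on the model features
is fit and explained, showing which feature patterns make a subject
informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "KernelConfig",
    "Explanation",
    "SummaryData",
    "kernel_weight",
    "kernel_shap",
    "exact_shap",
    "summarize",
    "force_data",
    "explain_valuations",
]


def kernel_weight(M: int, s: int) -> float:
    """Shapley kernel weight pi(M, s) = (M-1) / (C(M, s) * s * (M-s)).

    Defined for interior coalition sizes 0 < s < M; the boundary sizes have
    infinite weight and are handled as hard constraints by the solver.
    """
    if not 0 < s < M:
        raise ValueError("kernel weight is infinite for s in {0, M}")
    return (M - 1) / (math.comb(M, s) * s * (M - s))


@dataclass
class KernelConfig:
    """Kernel SHAP settings: coalition budget, regularization, background."""

    n_coalition_samples: int = 3000
    l1_reg: str | None = "auto"  # None, "auto": prune only when sampling
    max_background: int = 100
    seed: int = 0


@dataclass
class Explanation:
    """Per-feature Shapley attributions for one model prediction."""

    base_value: float          # average model output over the background
    values: np.ndarray         # per-feature attributions
    fx: float                  # model output for the explained instance
    feature_names: list[str]
    data: np.ndarray           # the explained instance's feature values

    @property
    def M(self) -> int:
        return len(self.values)

    def local_accuracy_gap(self) -> float:
        return abs(self.base_value + float(np.sum(self.values)) - self.fx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "phi": self.values, "value": self.data}
        )


def _coalition_values(
    predict, background: np.ndarray, x: np.ndarray, masks: np.ndarray,
    chunk_rows: int = 200_000,
) -> np.ndarray:
    """Mean model output per coalition, absent features imputed from the
    background rows."""
    B, M = background.shape
    out = np.empty(len(masks))
    per = max(1, chunk_rows // max(B, 1))
    for start in range(0, len(masks), per):
        sub = masks[start : start + per]
        # (k, B, M): background copies with present features set to x
        block = np.where(sub[:, None, :], x[None, None, :], background[None, :, :])
        preds = np.asarray(predict(block.reshape(-1, M)), dtype=float)
        out[start : start + per] = preds.reshape(len(sub), B).mean(axis=1)
    return out


def _all_masks(M: int) -> np.ndarray:
    ints = np.arange(1 << M)
    return (ints[:, None] >> np.arange(M)) & 1


def exact_shap(predict, background, x, max_M: int = 12) -> Explanation:
    """Shapley attributions by full enumeration of all 2^M coalitions.

    The coalition value is the mean model output with absent features
    imputed from the background rows; marginal contributions are combined
    with the exact binomial Shapley weights.  Refuses M > ``max_M``.
    """
    background = np.asarray(background, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    M = len(x)
    if M > max_M:
        raise ValueError(f"M={M} exceeds max_M={max_M}; use kernel_shap")
    masks = _all_masks(M).astype(bool)
    vals = _coalition_values(predict, background, x, masks)
    sizes = masks.sum(axis=1)
    w = np.array([1.0 / (M * math.comb(M - 1, s)) for s in range(M)])
    ints = np.arange(1 << M)
    phi = np.zeros(M)
    for i in range(M):
        bit = 1 << i
        without = ints[(ints & bit) == 0]
        phi[i] = np.sum((vals[without | bit] - vals[without]) * w[sizes[without]])
    fx = float(np.asarray(predict(x[None, :]), dtype=float)[0])
    names = [f"x{i}" for i in range(M)]
    return Explanation(float(vals[0]), phi, fx, names, x)


def _sample_masks(M: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Sample interior coalitions with size probability proportional to the
    aggregated Shapley kernel mass per size, uniform subsets within a size.

    Sampling proportional to the kernel makes the subsequent least squares
    unweighted (importance sampling)."""
    sizes = np.arange(1, M)
    p = (M - 1) / (sizes * (M - sizes))
    p = p / p.sum()
    drawn = rng.choice(sizes, size=n_samples, p=p)
    masks = np.zeros((n_samples, M), dtype=bool)
    for k, s in enumerate(drawn):
        masks[k, rng.choice(M, size=s, replace=False)] = True
    return masks


def _solve_constrained_wls(
    Z: np.ndarray, vals: np.ndarray, weights: np.ndarray,
    phi0: float, fx: float, active: np.ndarray,
) -> np.ndarray:
    """Weighted least squares with the efficiency constraint
    sum(phi[active]) = fx - phi0; inactive features are fixed at zero."""
    M = Z.shape[1]
    delta = fx - phi0
    act = np.flatnonzero(active)
    phi = np.zeros(M)
    if len(act) == 1:
        phi[act[0]] = delta
        return phi
    last = act[-1]
    rest = act[:-1]
    sw = np.sqrt(weights)
    A = (Z[:, rest].astype(float) - Z[:, [last]].astype(float)) * sw[:, None]
    r = (vals - phi0 - Z[:, last].astype(float) * delta) * sw
    coef, *_ = np.linalg.lstsq(A, r, rcond=None)
    phi[rest] = coef
    phi[last] = delta - coef.sum()
    return phi


def kernel_shap(
    predict, background, x, config: KernelConfig | None = None,
    feature_names: list[str] | None = None,
) -> Explanation:
    """Kernel SHAP attributions for one instance.

    Enumerates all 2^M - 2 interior coalitions when the sample budget
    allows (then the estimate equals the exact Shapley attribution of the
    imputation game); otherwise samples coalitions from the Shapley kernel.
    The boundary coalitions (empty / full) enter as hard constraints, so
    local accuracy phi0 + sum(phi) = f(x) holds exactly.  With ``l1_reg
    "auto"`` a least-angle regression pruning step is applied only in the
    sampling regime.
    """
    config = config or KernelConfig()
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = background[None, :]
    x = np.asarray(x, dtype=float).ravel()
    M = len(x)
    if config.n_coalition_samples < M + 2:
        raise ValueError("n_coalition_samples must be at least M + 2")
    rng = np.random.default_rng(config.seed)

    phi0 = float(np.mean(np.asarray(predict(background), dtype=float)))
    fx = float(np.asarray(predict(x[None, :]), dtype=float)[0])

    n_interior = (1 << M) - 2 if M <= 30 else np.inf
    complete = n_interior <= config.n_coalition_samples
    if complete:
        masks = _all_masks(M)[1:-1].astype(bool)
        sizes = masks.sum(axis=1)
        weights = np.array([kernel_weight(M, int(s)) for s in sizes])
    else:
        for attempt in range(5):
            masks = _sample_masks(M, config.n_coalition_samples, rng)
            if len(np.unique(masks, axis=0)) > 1:
                break
        else:
            raise RuntimeError("degenerate coalition sampling: all masks identical")
        weights = np.ones(len(masks))

    vals = _coalition_values(predict, background, x, masks)

    active = np.ones(M, dtype=bool)
    if config.l1_reg == "auto" and not complete:
        active = _lars_prune(masks, vals, weights, phi0)
    phi = _solve_constrained_wls(masks, vals, weights, phi0, fx, active)
    names = feature_names or [f"x{i}" for i in range(M)]
    return Explanation(phi0, phi, fx, list(names), x)


def _lars_prune(
    Z: np.ndarray, vals: np.ndarray, weights: np.ndarray, phi0: float
) -> np.ndarray:
    """AIC-guided least-angle selection of candidate nonzero attributions."""
    from sklearn.linear_model import LassoLarsIC

    sw = np.sqrt(weights)
    A = Z.astype(float) * sw[:, None]
    r = (vals - phi0) * sw
    try:
        sel = LassoLarsIC(criterion="aic").fit(A, r)
        active = np.abs(sel.coef_) > 0
    except Exception:
        return np.ones(Z.shape[1], dtype=bool)
    if active.sum() < 2:  # keep the problem solvable under the constraint
        return np.ones(Z.shape[1], dtype=bool)
    return active


# ---------------------------------------------------------------------------
# Display data
# ---------------------------------------------------------------------------


@dataclass
class SummaryData:
    """Aggregated explanations: importance ordering plus the point cloud."""

    importance: pd.DataFrame  # (feature, mean_abs_phi), non-increasing
    points: pd.DataFrame      # (feature, phi, displayed_value) long table

    @property
    def feature_order(self) -> list[str]:
        return self.importance["feature"].tolist()


def summarize(
    explanations: list[Explanation],
    normalize_columns: list[str] | None = None,
) -> SummaryData:
    """Order features by mean |phi| and collect the (phi, value) cloud.

    Displayed values for ``normalize_columns`` are min-max-normalized over
    the pooled explained instances.  Ties in mean |phi| order by feature
    name (stable).
    """
    if not explanations:
        raise ValueError("no explanations to summarize")
    names = explanations[0].feature_names
    phis = np.array([e.values for e in explanations])
    data = np.array([e.data for e in explanations], dtype=float)

    display = data.copy()
    if normalize_columns:
        for j, name in enumerate(names):
            if name in normalize_columns:
                lo, hi = data[:, j].min(), data[:, j].max()
                if hi > lo:
                    display[:, j] = (data[:, j] - lo) / (hi - lo)
                else:
                    display[:, j] = 0.0

    importance = (
        pd.DataFrame({"feature": names, "mean_abs_phi": np.abs(phis).mean(axis=0)})
        .sort_values(["mean_abs_phi", "feature"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    points = pd.DataFrame(
        {
            "feature": np.repeat(names, len(explanations)),
            "phi": phis.T.ravel(),
            "displayed_value": display.T.ravel(),
        }
    )
    return SummaryData(importance, points)


def force_data(explanation: Explanation) -> pd.DataFrame:
    """Force-plot arrows: (feature, phi, displayed value, direction).

    Positive attributions push the prediction up (pathogenic for the
    pMCI-probability output), negative ones down (protective).  Arrows are
    ordered by |phi| descending; zero attributions are omitted.  The base
    value plus all arrows reconstructs f(x).
    """
    df = explanation.to_frame()
    df = df[df["phi"] != 0].copy()
    df["direction"] = np.where(df["phi"] > 0, "pathogenic", "protective")
    df["abs_phi"] = df["phi"].abs()
    df = df.sort_values(["abs_phi", "feature"], ascending=[False, True],
                        kind="mergesort")
    return df.drop(columns="abs_phi").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Valuation explanation
# ---------------------------------------------------------------------------


def explain_valuations(
    X: pd.DataFrame,
    values: pd.Series,
    groups: pd.Series,
    config: KernelConfig | None = None,
    model_seed: int = 0,
    min_group_size: int = 10,
    normalize_columns: list[str] | None = None,
) -> dict[str, SummaryData]:
    """Which feature patterns make a subject's data informative?

    Per diagnostic group, fits a random-forest regressor (50 trees) of the
    per-subject data values on the model features and explains it with
    Kernel SHAP over the group's own rows (background subsampled to
    ``config.max_background``).  Groups smaller than ``min_group_size`` are
    skipped with a warning.
    """
    import warnings

    config = config or KernelConfig()
    values = pd.Series(values)
    groups = pd.Series(groups)
    out: dict[str, SummaryData] = {}
    for group in sorted(groups.unique()):
        ids = groups.index[groups == group]
        if len(ids) < min_group_size:
            warnings.warn(
                f"group {group!r} has {len(ids)} < {min_group_size} subjects; skipped"
            )
            continue
        Xg = X.loc[ids]
        model = RandomForestRegressor(
            n_estimators=50, random_state=model_seed, n_jobs=1
        )
        model.fit(Xg.to_numpy(dtype=float), values.loc[ids].to_numpy(dtype=float))
        rng = np.random.default_rng(config.seed)
        bg = Xg.to_numpy(dtype=float)
        if len(bg) > config.max_background:
            bg = bg[rng.choice(len(bg), size=config.max_background, replace=False)]
        explanations = [
            kernel_shap(
                model.predict, bg, Xg.loc[i].to_numpy(dtype=float), config,
                feature_names=list(X.columns),
            )
            for i in ids
        ]
        out[group] = summarize(explanations, normalize_columns=normalize_columns)
    return out
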