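"""Cohort assembly: subject selection, stratified splitting, preprocessing.

Selection follows the longitudinal labelling rules of the study cohort:
stable MCI (sMCI) subjects carry an MCI diagnosis at baseline and at every
follow-up; progressive MCI (pMCI) subjects convert to a stable AD diagnosis.
Subjects are excluded, in fixed flow order, when the baseline diagnosis is
not MCI, when no follow-up diagnosis exists, when any diagnosis reverts
(AD back to MCI/CN, or MCI back to CN), or when no baseline MRI is
available.

Splitting is stratified within each diagnostic group (65/15/20 by default)
and standardisation parameters are estimated on the training rows only and
re-applied unchanged to every other partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .synthetic import _round_half_away

__all__ = [
    "SelectionReport",
    "SplitAssignment",
    "Standardizer",
    "apply_selection_criteria",
    "stratified_split",
    "etiv_normalize",
    "fit_standardizer",
    "cohort_summary",
]


# ---------------------------------------------------------------------------
# Subject selection
# ---------------------------------------------------------------------------

CRITERIA = (
    "no MCI diagnosis at baseline",
    "no follow-up diagnosis",
    "diagnosis reverted at a follow-up visit",
    "no baseline MRI available",
)


@dataclass
class SelectionReport:
    """Exclusion flow: per-criterion counts plus the final class sizes."""

    n_initial: int
    steps: list[tuple[str, int, int]]  # (criterion, n_excluded, n_remaining)
    class_counts: dict[str, int]

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_initial

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "steps": [
                {"criterion": c, "n_excluded": e, "n_remaining": r}
                for c, e, r in self.steps
            ],
            "class_counts": dict(self.class_counts),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        lines = [f"{self.n_initial} subjects at entry"]
        for criterion, excluded, remaining in self.steps:
            lines.append(f"  - excluded {excluded:4d}: {criterion}")
            lines.append(f"  {remaining} subjects remaining")
        counts = ", ".join(f"{v} {k}" for k, v in self.class_counts.items())
        lines.append(f"final: {counts}")
        return "\n".join(lines)


def _classify_history(dx_after_baseline: list[str]) -> str:
    """Classify a baseline-MCI subject's follow-up history.

    Returns "sMCI", "pMCI", or "reverted".  A reversion is any improvement:
    AD followed by MCI or CN, or MCI followed by CN.
    """
    severity = {"CN": 0, "MCI": 1, "AD": 2}
    prev = severity["MCI"]  # baseline
    worst = prev
    for d in dx_after_baseline:
        s = severity[d]
        if s < worst:
            return "reverted"
        worst = max(worst, s)
    return "pMCI" if worst == severity["AD"] else "sMCI"


def apply_selection_criteria(
    visits: pd.DataFrame,
) -> tuple[pd.Series, SelectionReport]:
    """Derive sMCI/pMCI labels and the exclusion-flow report from visits.

    Exclusions are applied in fixed flow order so the per-criterion counts
    are comparable across cohorts.  Raises if a subject lacks a baseline
    (month 0) visit.
    """
    required = {"subject_id", "visit_month", "diagnosis", "mri_available_at_baseline"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visit table misses columns: {sorted(missing)}")

    visits = visits.sort_values(["subject_id", "visit_month"], kind="mergesort")
    groups = visits.groupby("subject_id", sort=True)
    n_initial = groups.ngroups

    non_mci, no_follow, reverted, no_mri = [], [], [], []
    labels: dict[str, str] = {}
    for sid, g in groups:
        months = g["visit_month"].to_numpy()
        if months[0] != 0:
            raise ValueError(f"subject {sid} has no baseline (month 0) visit")
        if np.any(np.diff(months) <= 0):
            raise ValueError(f"subject {sid} has non-increasing visit months")
        dx = g["diagnosis"].tolist()
        if dx[0] != "MCI":
            non_mci.append(sid)
            continue
        if len(dx) == 1:
            no_follow.append(sid)
            continue
        outcome = _classify_history(dx[1:])
        if outcome == "reverted":
            reverted.append(sid)
            continue
        if not bool(g["mri_available_at_baseline"].iloc[0]):
            no_mri.append(sid)
            continue
        labels[sid] = outcome

    steps = []
    remaining = n_initial
    for criterion, excluded in zip(
        CRITERIA, (non_mci, no_follow, reverted, no_mri)
    ):
        remaining -= len(excluded)
        steps.append((criterion, len(excluded), remaining))

    label_series = pd.Series(labels, name="label").sort_index()
    class_counts = {
        cls: int((label_series == cls).sum()) for cls in schema.CLASSES
    }
    return label_series, SelectionReport(n_initial, steps, class_counts)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    """Per-subject partition assignment with the fractions and seed used."""

    assignment: pd.Series  # subject_id -> {"train", "valid", "test"}
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> list:
        return list(self.assignment.index[self.assignment == part])

    def counts(self) -> dict[str, int]:
        return self.assignment.value_counts().to_dict()

    def to_frame(self) -> pd.DataFrame:
        return self.assignment.rename("partition").rename_axis("subject_id").reset_index()


def stratified_split(
    labels: pd.Series,
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20),
    seed: int = 0,
) -> SplitAssignment:
    """Split subjects into train/valid/test within each diagnostic group.

    Per class, ``n_train = round(f_train * n_c)`` and
    ``n_valid = round(f_valid * n_c)`` (half away from zero); the remainder
    goes to the test partition.  With the published class sizes (400, 319)
    and fractions (0.65, 0.15, 0.20), this yields totals 467/108/144.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=labels.index, dtype=object)
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if len(ids) == 0:
            raise ValueError(f"class {cls} is empty")
        n_c = len(ids)
        n_train = _round_half_away(fractions[0] * n_c)
        n_valid = _round_half_away(fractions[1] * n_c)
        if n_train + n_valid > n_c:
            raise ValueError(f"class {cls} too small for the requested fractions")
        perm = rng.permutation(ids)
        assignment[perm[:n_train]] = "train"
        assignment[perm[n_train : n_train + n_valid]] = "valid"
        assignment[perm[n_train + n_valid :]] = "test"
    return SplitAssignment(assignment, tuple(fractions), seed)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def etiv_normalize(features: pd.DataFrame) -> pd.DataFrame:
    """Divide each regional volume by the subject's eTIV.

    The raw eTIV column is retained as the final volumetric feature (a
    self-normalised eTIV would be a constant column).  Raises if any eTIV
    is non-positive, naming the offending subject.
    """
    out = features.copy()
    etiv = out[schema.ETIV].to_numpy(dtype=float)
    if np.any(etiv <= 0):
        bad = out.loc[etiv <= 0, schema.SUBJECT_ID].iloc[0]
        raise ValueError(f"non-positive eTIV for subject {bad}")
    regional = [c for c in schema.regional_volume_columns() if c in out.columns]
    out[regional] = out[regional].to_numpy(dtype=float) / etiv[:, None]
    return out


@dataclass
class Standardizer:
    """Per-feature centering/scaling estimated on training rows only."""

    center: pd.Series
    scale: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.center.index)

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        out[self.columns] = (rows[self.columns] - self.center) / self.scale
        return out

    def inverse_transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        out[self.columns] = rows[self.columns] * self.scale + self.center
        return out


def fit_standardizer(train: pd.DataFrame, columns: list[str] | None = None) -> Standardizer:
    """Estimate center (mean) and scale (sample SD) from training rows.

    Raises on zero-variance features, naming the first offender.
    """
    if columns is None:
        columns = [c for c in train.columns if pd.api.types.is_numeric_dtype(train[c])]
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    sub = train[columns].astype(float)
    center = sub.mean()
    scale = sub.std(ddof=0)  # population SD: {-1, +1} scales to exactly 1
    zero = scale.index[scale == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature: {zero[0]}")
    return Standardizer(center=center, scale=scale)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def cohort_summary(
    features: pd.DataFrame,
    labels: pd.Series,
    continuous: tuple[str, ...] = ("age", "MMSE", "LDELTOTAL", "LIMMTOTAL"),
    categorical: tuple[str, ...] = ("gender", "apoe4_count"),
) -> pd.DataFrame:
    """Per-class cohort summary in the style of a study demographics table.

    Continuous variables are reported as mean +- sd with a Mann-Whitney U
    p-value; categorical variables as per-level proportions with a chi-square
    p-value.  Degenerate classes are flagged and the p-value omitted.
    """
    labels = pd.Series(labels)
    feat = features.set_index(schema.SUBJECT_ID) if schema.SUBJECT_ID in features else features
    feat = feat.loc[labels.index]
    by_class = {cls: feat[labels == cls] for cls in schema.CLASSES}
    rows = []
    for cls, sub in by_class.items():
        if len(sub) < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects")

    for var in continuous:
        a = by_class[schema.CLASSES[0]][var].astype(float)
        b = by_class[schema.CLASSES[1]][var].astype(float)
        degenerate = a.nunique() <= 1 and b.nunique() <= 1
        if degenerate and a.iloc[0] == b.iloc[0]:
            p = np.nan
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                f"{schema.CLASSES[0]}": f"{a.mean():.1f} ±{a.std(ddof=1):.1f}",
                f"{schema.CLASSES[1]}": f"{b.mean():.1f} ±{b.std(ddof=1):.1f}",
                "p_value": p,
            }
        )
    for var in categorical:
        table = pd.crosstab(feat[var], labels)
        if table.shape[0] < 2:
            p = np.nan  # single level in both classes: test undefined
        else:
            p = stats.chi2_contingency(table.to_numpy()).pvalue
        for level in table.index:
            rows.append(
                {
                    "variable": f"{var}={level}",
                    "type": "categorical",
                    f"{schema.CLASSES[0]}": f"{100 * table.loc[level, schema.CLASSES[0]] / len(by_class[schema.CLASSES[0]]):.1f}%",
                    f"{schema.CLASSES[1]}": f"{100 * table.loc[level, schema.CLASSES[1]] / len(by_class[schema.CLASSES[1]]):.1f}%",
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
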