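"""Random-forest importance feature filtering and model-matrix assembly.

MRI volumetric features are ranked by impurity-based random-forest
importance computed on training rows only; the mean importance over all
features is the retention threshold (features strictly below the mean are
dropped).  The surviving MRI features are then expanded with three
demographic features and three cognitive test scores to form the model
matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import schema

__all__ = [
    "rf_importance_rank",
    "mean_threshold_filter",
    "assemble_model_matrix",
    "encode_clinical",
]

# The only RF size stated for the workflow.
RF_N_ESTIMATORS = 50


def rf_importance_rank(
    mri_features: pd.DataFrame, labels: pd.Series, seed: int = 0
) -> pd.DataFrame:
    """Impurity-based RF importances for each MRI feature.

    Fits a random forest (50 trees, gini) on the training rows only and
    returns a table of (feature, importance) sorted by descending
    importance.  Importances are non-negative and sum to 1.
    """
    labels = pd.Series(labels)
    if labels.nunique() < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=RF_N_ESTIMATORS,
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(mri_features.to_numpy(dtype=float), labels.to_numpy())
    table = pd.DataFrame(
        {"feature": mri_features.columns, "importance": model.feature_importances_}
    )
    return table.sort_values(
        ["importance", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def mean_threshold_filter(importances: pd.DataFrame) -> list[str]:
    """Keep features whose importance is >= the mean importance.

    Features strictly smaller than the mean are excluded; a tie at the
    threshold is retained.  Order of the returned names follows the input
    table.
    """
    if len(importances) == 0:
        raise ValueError("empty importance table")
    threshold = importances["importance"].mean()
    keep = importances["importance"] >= threshold
    return importances.loc[keep, "feature"].tolist()


def encode_clinical(features: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical block: gender as a binary indicator
    (female = 1), ApoE e4 count as an ordinal integer."""
    out = features.copy()
    if out["gender"].dtype == object:
        out["gender"] = (out["gender"] == "female").astype(int)
    if not pd.api.types.is_float_dtype(out["apoe4_count"]):
        out["apoe4_count"] = out["apoe4_count"].astype(int)
    return out


def assemble_model_matrix(
    features: pd.DataFrame, selected_mri: list[str]
) -> pd.DataFrame:
    """Model matrix: selected MRI features, then age, gender, apoe4_count,
    MMSE, LDELTOTAL, LIMMTOTAL — in that fixed column order."""
    columns = list(selected_mri) + list(schema.CLINICAL_FEATURES)
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise KeyError(f"missing column: {missing[0]}")
    out = encode_clinical(features)[columns]
    if schema.SUBJECT_ID in features.columns:
        out.index = pd.Index(features[schema.SUBJECT_ID], name=schema.SUBJECT_ID)
    return out
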