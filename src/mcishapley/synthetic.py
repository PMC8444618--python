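"""Synthetic ADNI/AIBL-like cohort generator.

Emulates the two tables the real workflow starts from: a longitudinal visit
table (baseline + follow-up diagnoses in {CN, MCI, AD} with an MRI
availability flag) and a per-subject feature table (102 regional brain
volumes + eTIV, three demographic features, three cognitive scores, and a
stable/progressive MCI label).  Class-conditional structure follows the
published cohort summaries: progressive subjects have lower cognitive
scores, more ApoE e4 alleles, smaller grey-matter volumes, and larger
ventricles.  A label-noise planting utility provides ground truth for
data-valuation recovery experiments.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import schema

__all__ = [
    "GeneratorConfig",
    "generate_visit_table",
    "generate_feature_table",
    "plant_label_noise",
    "planted_category_counts",
]


def _round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Class-conditional parameters are ``(sMCI, pMCI)`` pairs.  Defaults
    reproduce the published ADNI cohort structure: a 2250-subject funnel
    whose selection flow leaves 719 classifiable subjects (400 sMCI /
    319 pMCI), with class summaries (MMSE, age, gender, ApoE e4 allele
    distribution) matching the cohort table.
    """

    n_subjects: int = 2250
    class_balance: float = 319 / 719  # fraction pMCI among classifiable MCI
    n_regional_volumes: int = 102

    # Visit-table realism fractions (of n_subjects, selection-flow order).
    non_mci_baseline_fraction: float = 1219 / 2250
    no_followup_fraction: float = 124 / 2250
    reversion_fraction: float = 101 / 2250
    missing_mri_fraction: float = 87 / 2250

    # Volumes.
    etiv_mean: float = 1.5e6
    etiv_sd: float = 1.5e5
    volume_cv: float = 0.12          # per-region SD as fraction of the mean
    latent_loading: float = 0.5      # shared "atrophy severity" factor loading
    volume_effect_size: float | dict[str, float] | None = None
    # None -> built per region: AD-signature regions d=0.5, ventricles d=-0.35
    # (enlarged in pMCI), remaining regions d=0.15.

    # Cognitive scores (integer-valued instruments, clipped to range).
    mmse_mean: tuple[float, float] = (27.8, 27.0)
    mmse_sd: tuple[float, float] = (1.8, 1.7)
    ldeltotal_mean: tuple[float, float] = (8.0, 4.5)
    ldeltotal_sd: tuple[float, float] = (3.5, 3.0)
    limmtotal_mean: tuple[float, float] = (11.0, 8.0)
    limmtotal_sd: tuple[float, float] = (4.0, 3.5)

    # Demographics.
    age_mean: tuple[float, float] = (73.2, 74.0)
    age_sd: tuple[float, float] = (7.5, 7.1)
    female_fraction: tuple[float, float] = (0.403, 0.401)
    apoe_probs: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.568, 0.340, 0.092),
        (0.342, 0.495, 0.163),
    )

    label_noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if not 1 <= self.n_regional_volumes <= 102:
            raise ValueError("n_regional_volumes must be in 1..102")
        fractions = {
            "non_mci_baseline_fraction": self.non_mci_baseline_fraction,
            "no_followup_fraction": self.no_followup_fraction,
            "reversion_fraction": self.reversion_fraction,
            "missing_mri_fraction": self.missing_mri_fraction,
            "label_noise_fraction": self.label_noise_fraction,
        }
        for name, f in fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        excluded = (
            self.non_mci_baseline_fraction
            + self.no_followup_fraction
            + self.reversion_fraction
            + self.missing_mri_fraction
        )
        if excluded >= 1.0:
            raise ValueError("exclusion fractions leave no classifiable subjects")
        for probs in self.apoe_probs:
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ValueError("apoe_probs must be two non-negative 3-vectors")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError("apoe_probs must sum to 1 within 1e-12")
        for f in self.female_fraction:
            if not 0.0 <= f <= 1.0:
                raise ValueError("female_fraction must be in [0, 1]")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in (
            "mmse_mean", "mmse_sd", "ldeltotal_mean", "ldeltotal_sd",
            "limmtotal_mean", "limmtotal_sd", "age_mean", "age_sd",
            "female_fraction",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "apoe_probs" in d and d["apoe_probs"] is not None:
            d["apoe_probs"] = tuple(tuple(p) for p in d["apoe_probs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls.from_dict(data)

    # -- derived schema ---------------------------------------------------
    def regional_columns(self) -> list[str]:
        return schema.regional_volume_columns()[: self.n_regional_volumes]

    def effect_sizes(self) -> np.ndarray:
        """Standardised sMCI-minus-pMCI mean shift per regional volume.

        Positive values mean the region is smaller in pMCI (atrophy);
        negative values mean it is larger (ventricular enlargement).
        """
        cols = self.regional_columns()
        spec_d = self.volume_effect_size
        if spec_d is None:
            d = np.full(len(cols), 0.15)
            for j, c in enumerate(cols):
                if c in schema.AD_SIGNATURE_REGIONS:
                    d[j] = 0.5
                elif c in schema.VENTRICLE_REGIONS:
                    d[j] = -0.35
            return d
        if isinstance(spec_d, dict):
            return np.array([float(spec_d.get(c, 0.0)) for c in cols])
        return np.full(len(cols), float(spec_d))


# Representative volumes (mm^3) for the subcortical / global segmentations.
_SUBCORTICAL_MEANS = {
    "Left-Hippocampus": 4200.0, "Right-Hippocampus": 4300.0,
    "Left-Amygdala": 1600.0, "Right-Amygdala": 1700.0,
    "Left-Thalamus-Proper": 7100.0, "Right-Thalamus-Proper": 7000.0,
    "Left-Caudate": 3600.0, "Right-Caudate": 3700.0,
    "Left-Putamen": 4900.0, "Right-Putamen": 4800.0,
    "Left-Pallidum": 1800.0, "Right-Pallidum": 1750.0,
    "Left-Accumbens-area": 600.0, "Right-Accumbens-area": 620.0,
    "Left-VentralDC": 4000.0, "Right-VentralDC": 4050.0,
    "Left-Cerebellum-Cortex": 52000.0, "Right-Cerebellum-Cortex": 53000.0,
    "Left-Cerebellum-White-Matter": 14000.0, "Right-Cerebellum-White-Matter": 14200.0,
    "Left-Lateral-Ventricle": 12000.0, "Right-Lateral-Ventricle": 11000.0,
    "Left-Inf-Lat-Vent": 500.0, "Right-Inf-Lat-Vent": 450.0,
    "3rd-Ventricle": 1300.0, "4th-Ventricle": 1700.0,
    "Brain-Stem": 21000.0,
    "CC_Posterior": 950.0, "CC_Mid_Posterior": 450.0, "CC_Central": 480.0,
    "CC_Mid_Anterior": 470.0, "CC_Anterior": 850.0,
    "lhCortexVol": 220000.0, "rhCortexVol": 221000.0,
}


def _volume_means(columns: list[str]) -> np.ndarray:
    """Deterministic per-region reference means (mm^3)."""
    means = np.empty(len(columns))
    cortical_index = 0
    for j, c in enumerate(columns):
        if c in _SUBCORTICAL_MEANS:
            means[j] = _SUBCORTICAL_MEANS[c]
        else:
            # Cortical parcels: spread 2500..12500 mm^3, lh/rh paired.
            region_rank = cortical_index % len(schema.CORTICAL_REGIONS)
            means[j] = 2500.0 + 300.0 * region_rank
            cortical_index += 1
    return means


# ---------------------------------------------------------------------------
# Visit table
# ---------------------------------------------------------------------------

_CATEGORIES = ("non_mci", "no_followup", "reverter", "missing_mri", "sMCI", "pMCI")


def planted_category_counts(config: GeneratorConfig) -> dict[str, int]:
    """Exact subject counts per planted visit-history category."""
    n = config.n_subjects
    counts = {
        "non_mci": _round_half_away(config.non_mci_baseline_fraction * n),
        "no_followup": _round_half_away(config.no_followup_fraction * n),
        "reverter": _round_half_away(config.reversion_fraction * n),
        "missing_mri": _round_half_away(config.missing_mri_fraction * n),
    }
    classifiable = n - sum(counts.values())
    if classifiable < 0:
        raise ValueError("exclusion fractions exceed the cohort size")
    n_pmci = _round_half_away(config.class_balance * classifiable)
    counts["pMCI"] = n_pmci
    counts["sMCI"] = classifiable - n_pmci
    return counts


def _subject_categories(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    counts = planted_category_counts(config)
    cats = np.repeat(
        np.array(_CATEGORIES, dtype=object),
        [counts[c] for c in _CATEGORIES],
    )
    return rng.permutation(cats)


def _visit_rows(subject: str, category: str, class_balance: float,
                rng: np.random.Generator) -> list[tuple]:
    """Visit history for one subject; visits every 6 months from baseline."""
    mri = category != "missing_mri"
    if category == "non_mci":
        base = "CN" if rng.random() < 0.5 else "AD"
        months = 6 * np.arange(rng.integers(1, 6) + 1)
        return [(subject, int(m), base, mri) for m in months]
    if category == "no_followup":
        return [(subject, 0, "MCI", mri)]

    n_follow = int(rng.integers(2, 8))  # follow-up visits
    months = 6 * np.arange(n_follow + 1)
    if category == "missing_mri":
        category = "pMCI" if rng.random() < class_balance else "sMCI"
    if category == "sMCI":
        dx = ["MCI"] * (n_follow + 1)
    elif category == "pMCI":
        conv = int(rng.integers(1, n_follow + 1))
        dx = ["MCI"] * conv + ["AD"] * (n_follow + 1 - conv)
    else:  # reverter
        style = rng.integers(0, 2)
        if style == 0 or n_follow < 2:
            # MCI -> CN reversion at a random follow-up visit.
            rev = int(rng.integers(1, n_follow + 1))
            dx = ["MCI"] * rev + ["CN"] * (n_follow + 1 - rev)
        else:
            # converted to AD but reverted afterwards
            conv = int(rng.integers(1, n_follow))
            dx = ["MCI"] * conv + ["AD"] * (n_follow - conv) + ["MCI"]
    return [(subject, int(m), d, mri) for m, d in zip(months, dx)]


def generate_visit_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the longitudinal visit table.

    Columns: ``subject_id, visit_month, diagnosis, mri_available_at_baseline``.
    Every subject has exactly one baseline (month 0) visit and strictly
    increasing visit months.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    categories = _subject_categories(config, rng)
    width = max(4, len(str(config.n_subjects)))
    rows: list[tuple] = []
    for i, cat in enumerate(categories):
        sid = f"SYN{i:0{width}d}"
        rows.extend(_visit_rows(sid, cat, config.class_balance, rng))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "visit_month", "diagnosis", "mri_available_at_baseline"],
    )


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


def generate_feature_table(config: GeneratorConfig, labels: pd.Series) -> pd.DataFrame:
    """Generate the per-subject feature table for labelled subjects.

    ``labels`` maps subject_id -> {"sMCI", "pMCI"}.  Volumes are drawn from
    truncated-at-zero Gaussians with a shared per-subject atrophy factor;
    cognitive scores are integer-rounded and clipped to instrument ranges;
    ApoE e4 allele count and gender are categorical draws from the per-class
    probabilities.  Deterministic given ``config.seed``.
    """
    config.validate()
    labels = pd.Series(labels)
    bad = set(labels.unique()) - set(schema.CLASSES)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    rng = np.random.default_rng([config.seed, 2])

    subjects = labels.index.to_numpy()
    y = (labels.to_numpy() == schema.POSITIVE_CLASS).astype(int)  # 0 sMCI, 1 pMCI
    n = len(subjects)

    cols = config.regional_columns()
    means = _volume_means(cols)
    sds = config.volume_cv * means
    d = config.effect_sizes()

    lam = config.latent_loading
    atrophy = rng.standard_normal(n)  # shared severity factor per subject
    noise = rng.standard_normal((n, len(cols)))
    direction = np.where(d < 0, -1.0, 1.0)  # ventricles load negatively
    z = lam * np.outer(atrophy, direction) + np.sqrt(1 - lam**2) * noise
    z -= np.outer(y, d)  # pMCI shifted by -d (smaller when d>0)
    volumes = means + sds * z
    np.maximum(volumes, 0.01 * means, out=volumes)  # truncate at (near) zero

    etiv = config.etiv_mean + config.etiv_sd * rng.standard_normal(n)
    np.maximum(etiv, 0.01 * config.etiv_mean, out=etiv)

    def gaussian(mean, sd):
        m = np.where(y == 0, mean[0], mean[1])
        s = np.where(y == 0, sd[0], sd[1])
        return m + s * rng.standard_normal(n)

    age = np.round(gaussian(config.age_mean, config.age_sd), 1)
    mmse = np.clip(np.rint(gaussian(config.mmse_mean, config.mmse_sd)), 0, 30)
    ldel = np.clip(np.rint(gaussian(config.ldeltotal_mean, config.ldeltotal_sd)), 0, 25)
    limm = np.clip(np.rint(gaussian(config.limmtotal_mean, config.limmtotal_sd)), 0, 25)

    female_p = np.where(y == 0, config.female_fraction[0], config.female_fraction[1])
    gender = np.where(rng.random(n) < female_p, "female", "male")

    apoe = np.empty(n, dtype=int)
    u = rng.random(n)
    for cls in (0, 1):
        cum = np.cumsum(config.apoe_probs[cls])
        mask = y == cls
        apoe[mask] = np.searchsorted(cum, u[mask], side="right")
    apoe = np.clip(apoe, 0, 2)

    table = pd.concat(
        [
            pd.DataFrame({"subject_id": subjects}),
            pd.DataFrame(volumes, columns=cols),
            pd.DataFrame(
                {
                    schema.ETIV: etiv,
                    "age": age,
                    "gender": gender,
                    "apoe4_count": apoe,
                    "MMSE": mmse.astype(int),
                    "LDELTOTAL": ldel.astype(int),
                    "LIMMTOTAL": limm.astype(int),
                    schema.LABEL_COLUMN: labels.to_numpy(),
                }
            ),
        ],
        axis=1,
    )
    return table


def plant_label_noise(
    labels: pd.Series, fraction: float, seed: int
) -> tuple[pd.Series, list]:
    """Flip exactly ``round(fraction * n)`` labels, chosen uniformly.

    Returns the noisy labels and the ids of flipped subjects.  Deterministic
    given ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    labels = pd.Series(labels)
    n_flip = _round_half_away(fraction * len(labels))
    rng = np.random.default_rng(seed)
    flipped_idx = rng.choice(len(labels), size=n_flip, replace=False)
    flip_map = {schema.CLASSES[0]: schema.CLASSES[1],
                schema.CLASSES[1]: schema.CLASSES[0]}
    noisy = labels.copy()
    positions = noisy.index[np.sort(flipped_idx)]
    noisy.loc[positions] = [flip_map[v] for v in noisy.loc[positions]]
    return noisy, list(positions)
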