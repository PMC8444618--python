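"""Column schema for the volumetric / clinical feature tables.

The model matrix mirrors a FreeSurfer volumetric export: 34 cortical
parcellation volumes per hemisphere, 34 subcortical / global segmentation
volumes, and the estimated Total Intracranial Volume (eTIV) — 103 volumetric
features in total — plus three demographic features and three cognitive test
scores.
"""

from __future__ import annotations

# Cortical parcellation units (one per hemisphere).
CORTICAL_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

# Subcortical and global segmentation volumes.
SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "Left-Hippocampus",
    "Right-Hippocampus",
    "Left-Amygdala",
    "Right-Amygdala",
    "Left-Thalamus-Proper",
    "Right-Thalamus-Proper",
    "Left-Caudate",
    "Right-Caudate",
    "Left-Putamen",
    "Right-Putamen",
    "Left-Pallidum",
    "Right-Pallidum",
    "Left-Accumbens-area",
    "Right-Accumbens-area",
    "Left-VentralDC",
    "Right-VentralDC",
    "Left-Cerebellum-Cortex",
    "Right-Cerebellum-Cortex",
    "Left-Cerebellum-White-Matter",
    "Right-Cerebellum-White-Matter",
    "Left-Lateral-Ventricle",
    "Right-Lateral-Ventricle",
    "Left-Inf-Lat-Vent",
    "Right-Inf-Lat-Vent",
    "3rd-Ventricle",
    "4th-Ventricle",
    "Brain-Stem",
    "CC_Posterior",
    "CC_Mid_Posterior",
    "CC_Central",
    "CC_Mid_Anterior",
    "CC_Anterior",
    "lhCortexVol",
    "rhCortexVol",
)

# Regions that enlarge (rather than atrophy) with disease progression.
VENTRICLE_REGIONS: frozenset[str] = frozenset(
    {
        "Left-Lateral-Ventricle",
        "Right-Lateral-Ventricle",
        "Left-Inf-Lat-Vent",
        "Right-Inf-Lat-Vent",
        "3rd-Ventricle",
        "4th-Ventricle",
    }
)

# The classic AD atrophy signature: medial-temporal structures.
AD_SIGNATURE_REGIONS: frozenset[str] = frozenset(
    {
        "Left-Hippocampus",
        "Right-Hippocampus",
        "Left-Amygdala",
        "Right-Amygdala",
        "lh_entorhinal_volume",
        "rh_entorhinal_volume",
        "lh_middletemporal_volume",
        "rh_middletemporal_volume",
        "lh_fusiform_volume",
        "rh_fusiform_volume",
        "lh_parahippocampal_volume",
        "rh_parahippocampal_volume",
        "lh_inferiortemporal_volume",
        "rh_inferiortemporal_volume",
    }
)

ETIV = "eTIV"
DEMOGRAPHIC_FEATURES: tuple[str, ...] = ("age", "gender", "apoe4_count")
COGNITIVE_FEATURES: tuple[str, ...] = ("MMSE", "LDELTOTAL", "LIMMTOTAL")
CLINICAL_FEATURES: tuple[str, ...] = DEMOGRAPHIC_FEATURES + COGNITIVE_FEATURES

LABEL_COLUMN = "label"
SUBJECT_ID = "subject_id"
CLASSES: tuple[str, str] = ("sMCI", "pMCI")
POSITIVE_CLASS = "pMCI"

DIAGNOSES: tuple[str, str, str] = ("CN", "MCI", "AD")


def regional_volume_columns() -> list[str]:
    """The 102 regional volume column names (cortical lh/rh + subcortical)."""
    cols = [f"lh_{r}_volume" for r in CORTICAL_REGIONS]
    cols += [f"rh_{r}_volume" for r in CORTICAL_REGIONS]
    cols += list(SUBCORTICAL_REGIONS)
    return cols


def volumetric_columns() -> list[str]:
    """All 103 volumetric feature names: 102 regional volumes plus eTIV."""
    return regional_volume_columns() + [ETIV]


def feature_table_columns() -> list[str]:
    return [SUBJECT_ID, *volumetric_columns(), *CLINICAL_FEATURES, LABEL_COLUMN]
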