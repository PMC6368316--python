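"""Published group summary statistics used as simulation defaults.

The reference study of pediatric osteosarcoma reported per-feature
mean +/- SD for 24 metastatic vs 18 non-metastatic pulmonary nodules
(total group) and for the 7 vs 18 split among small (<= 5 mm)
non-calcified nodules.  These summaries are the only distributional
anchor available for feature-level simulation, so they are recorded
here verbatim and used as the default :class:`~nodtex.synthetic_data.CohortSpec`
parameters.

Each table maps feature name -> ((mean_met, sd_met), (mean_non, sd_non)).
"""

from __future__ import annotations

#: Canonical order of the 15 texture/morphology features.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_attenuation",
    "attenuation_sd",
    "attenuation_variance",
    "skewness",
    "kurtosis",
    "effective_diameter",
    "surface_area",
    "volume",
    "sphericity",
    "discrete_compactness",
    "glcm_moments",
    "glcm_asm",
    "glcm_idm",
    "glcm_contrast",
    "glcm_entropy",
)

#: Metadata columns carried alongside the features in a cohort table.
METADATA_COLUMNS: tuple[str, ...] = ("nodule_id", "label", "calcified", "subgroup")

#: Group labels used throughout.
LABEL_METASTASIS = "metastasis"
LABEL_NON_METASTASIS = "non_metastasis"

#: Total group (24 metastatic / 18 non-metastatic nodules).
TOTAL_GROUP_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "mean_attenuation": ((51.4, 198.6), (-242.4, 75.7)),
    "attenuation_sd": ((272.0, 146.9), (159.6, 39.6)),
    "attenuation_variance": ((94666.4, 116166.8), (27196.7, 13103.8)),
    "skewness": ((-0.069, 0.488), (0.2334, 0.512)),
    "kurtosis": ((-0.214, 0.924), (-0.578, 0.773)),
    "effective_diameter": ((10.1, 11.1), (2.0, 0.9)),
    "surface_area": ((410.0, 620.1), (36.4, 26.2)),
    "volume": ((695.6, 1507.2), (15.8, 14.6)),
    "sphericity": ((0.777, 0.151), (0.821, 0.091)),
    "discrete_compactness": ((-0.003, 0.558), (-0.990, 0.699)),
    "glcm_moments": ((1.9, 0.2), (1.8, 0.3)),
    "glcm_asm": ((0.001, 0.003), (0.007, 0.006)),
    "glcm_idm": ((0.006, 0.003), (0.003, 0.003)),
    "glcm_contrast": ((124301.1, 121736.8), (86076.5, 14546.1)),
    "glcm_entropy": ((3.4, 0.8), (2.3, 0.4)),
}

#: Small (<= 5 mm) non-calcified subgroup (7 metastatic / 18 non-metastatic).
SUBGROUP_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "mean_attenuation": ((-116.5, 91.8), (-242.4, 75.7)),
    "attenuation_sd": ((195.6, 40.0), (159.6, 39.6)),
    "attenuation_variance": ((39658.2, 15900.2), (27196.7, 13103.8)),
    "skewness": ((-0.191, 0.252), (0.233, 0.512)),
    "kurtosis": ((-1.031, 0.213), (-0.578, 0.773)),
    "effective_diameter": ((3.4, 1.7), (2.0, 0.9)),
    "surface_area": ((75.5, 49.5), (36.4, 26.2)),
    "volume": ((45.0, 35.9), (15.8, 14.6)),
    "sphericity": ((0.863, 0.091), (0.821, 0.091)),
    "discrete_compactness": ((-0.403, 0.716), (-0.990, 0.699)),
    "glcm_moments": ((1.9, 0.3), (1.8, 0.3)),
    "glcm_asm": ((0.004, 0.005), (0.007, 0.006)),
    "glcm_idm": ((0.005, 0.005), (0.003, 0.003)),
    "glcm_contrast": ((96101.5, 44711.6), (86076.5, 14546.1)),
    "glcm_entropy": ((2.6, 0.5), (2.3, 0.4)),
}

#: Study composition: (n metastatic, n non-metastatic).
TOTAL_GROUP_SIZES: tuple[int, int] = (24, 18)
SUBGROUP_SIZES: tuple[int, int] = (7, 18)

#: Subgroup eligibility rule: effective diameter at or below this (mm),
#: and no calcification.
SUBGROUP_DIAMETER_MM: float = 5.0
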