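"""Frozen registry of the 83-feature texture panel.

The panel is partitioned into 20 first-order, 22 second-order (GLCM),
35 higher-order (16 GLRLM + 14 GLSZM + 5 NGTDM) and 6 model-based
(fractal) features. The roster is a fixed design choice of this
package: the family sizes and the twelve survival-screen members are
contractual, and the remaining members complete each family with the
classical feature set a PET radiomics practitioner would expect.
"""

from __future__ import annotations

FIRST_ORDER = (
    "suv_min",
    "suv_max",
    "suv_mean",
    "suv_median",
    "suv_sd",
    "suv_variance",
    "fo_skewness",
    "fo_kurtosis",
    "fo_energy",
    "fo_entropy",
    "fo_uniformity",
    "suv_range",
    "fo_mad",
    "fo_rms",
    "suv_p10",
    "suv_p90",
    "suv_iqr",
    "fo_cov",
    "matv",
    "tlg",
)

GLCM = (
    "glcm_autocorrelation",
    "glcm_joint_average",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_average",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_dissimilarity",
    "glcm_idm",
    "glcm_idmn",
    "glcm_idn",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_inverse_variance",
    "glcm_max_probability",
    "glcm_sum_entropy",
)

GLRLM = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_glnn",
    "glrlm_rln",
    "glrlm_rlnn",
    "glrlm_rp",
    "glrlm_glv",
    "glrlm_rv",
    "glrlm_re",
    "glrlm_lglre",
    "glrlm_hglre",
    "glrlm_srlgle",
    "glrlm_srhgle",
    "glrlm_lrlgle",
    "glrlm_lrhgle",
)

GLSZM = (
    "glszm_sae",
    "glszm_lae",
    "glszm_intensity_variability",
    "glszm_glnn",
    "glszm_szn",
    "glszm_sznn",
    "glszm_zp",
    "glszm_glv",
    "glszm_zv",
    "glszm_ze",
    "glszm_lglze",
    "glszm_hglze",
    "glszm_salgle",
    "glszm_sahgle",
)

NGTDM = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

HIGHER_ORDER = GLRLM + GLSZM + NGTDM

FRACTAL = (
    "fractal_dbc_dimension",
    "fractal_mask_dimension",
    "fractal_boundary_dimension",
    "fractal_lacunarity_b2",
    "fractal_lacunarity_b4",
    "fractal_lacunarity_slope",
)

FAMILIES: dict[str, tuple[str, ...]] = {
    "first_order": FIRST_ORDER,
    "glcm": GLCM,
    "higher_order": HIGHER_ORDER,
    "fractal": FRACTAL,
}

FAMILY_SIZES = {"first_order": 20, "glcm": 22, "higher_order": 35, "fractal": 6}

ALL_FEATURES: tuple[str, ...] = FIRST_ORDER + GLCM + HIGHER_ORDER + FRACTAL

FAMILY_OF: dict[str, str] = {
    name: fam for fam, names in FAMILIES.items() for name in names
}

#: The 12 features entering the univariate Cox survival screen.
SCREEN_FEATURES = (
    "matv",
    "tlg",
    "suv_mean",
    "suv_max",
    "suv_sd",
    "fo_entropy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_dissimilarity",
    "glszm_intensity_variability",
    "ngtdm_coarseness",
    "ngtdm_contrast",
)

assert len(ALL_FEATURES) == 83
assert len(set(ALL_FEATURES)) == 83
assert all(len(FAMILIES[f]) == n for f, n in FAMILY_SIZES.items())
assert all(f in ALL_FEATURES for f in SCREEN_FEATURES)
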