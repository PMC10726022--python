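"""Published yearling Anatolian buffalo estimates used as analysis inputs.

These are the published variance components, heritabilities, genetic
correlations and genotype counts for the yearling Anatolian buffalo
population (313 calves across 36 farms).  They serve two purposes:

* as *inputs* to downstream arithmetic — selection-response prediction
  and heritability reconstruction operate on these printed estimates;
* as realistic defaults for the synthetic-herd generator, so simulated
  data carry the variance structure and fixed-effect contrasts of the
  real population.

Traits: BW body weight (kg); WH wither height, RH rump height, BL body
length, CW chest width, HW hip width, CC chest circumference, CBC
cannon-bone circumference (cm); LMA longissimus muscle area (cm^2);
LMD longissimus muscle depth (cm); SFT subcutaneous fat thickness (cm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "VARIANCE_COMPONENTS",
    "GENETIC_CORRELATIONS",
    "PHENOTYPIC_CORRELATIONS",
    "RESPONSE_MATRIX",
    "OVERALL_MEANS",
    "FIXED_EFFECT_CONTRASTS",
    "SNP_GENOTYPE_COUNTS",
    "genetic_correlation_frame",
    "phenotypic_correlation_frame",
    "response_matrix_frame",
]

TRAITS = ("BW", "WH", "RH", "BL", "CW", "HW", "CC", "CBC", "LMA", "LMD", "SFT")

#: Published variance components and heritabilities per trait:
#: columns sigma2_a, sigma2_m, sigma2_e, sigma2_p, h2_a, h2_m, h2_T, n.
VARIANCE_COMPONENTS = pd.DataFrame(
    {
        "sigma2_a": [260.172, 10.391, 12.321, 13.746, 3.612, 4.536, 29.698,
                     0.248, 0.016, 0.053, 0.004],
        "sigma2_m": [503.610, 0.002, 0.923, 9.111, 2.337, 2.685, 28.433,
                     0.837, 0.010, 0.088, 0.002],
        "sigma2_e": [16.163, 11.139, 12.812, 8.296, 3.982, 3.275, 10.173,
                     0.014, 15.291, 0.036, 0.001],
        "sigma2_p": [779.945, 21.534, 26.056, 31.153, 9.931, 10.498, 68.305,
                     1.099, 15.294, 0.178, 0.008],
        "h2_a": [0.334, 0.483, 0.473, 0.441, 0.364, 0.432, 0.435, 0.226,
                 0.0001, 0.300, 0.539],
        "h2_m": [0.646, 0.000, 0.035, 0.292, 0.235, 0.256, 0.416, 0.761,
                 0.000, 0.496, 0.315],
        "h2_T": [0.656, 0.483, 0.491, 0.587, 0.481, 0.560, 0.643, 0.606,
                 0.001, 0.547, 0.697],
        "n": [261, 272, 272, 272, 272, 272, 272, 272, 104, 313, 313],
    },
    index=pd.Index(TRAITS, name="trait"),
)

#: Published genetic correlations, upper triangle by trait order.
_RG_UPPER = {
    "BW": [0.78, 0.79, 0.82, 0.69, 0.62, 0.88, 0.76, 0.71, 0.75, 0.65],
    "WH": [0.90, 0.75, 0.51, 0.54, 0.76, 0.63, 0.51, 0.56, 0.50],
    "RH": [0.75, 0.53, 0.56, 0.78, 0.67, 0.53, 0.59, 0.52],
    "BL": [0.51, 0.57, 0.72, 0.67, 0.62, 0.64, 0.54],
    "CW": [0.02, 0.63, 0.55, 0.38, 0.57, 0.46],
    "HW": [0.60, 0.60, 0.46, 0.45, 0.49],
    "CC": [0.74, 0.65, 0.67, 0.59],
    "CBC": [0.68, 0.67, 0.61],
    "LMA": [0.82, 0.56],
    "LMD": [0.53],
}

#: Published phenotypic correlations, lower triangle rows (same order).
_RP_LOWER = {
    "WH": [0.73],
    "RH": [0.77, 0.90],
    "BL": [0.77, 0.75, 0.75],
    "CW": [0.69, 0.51, 0.53, 0.51],
    "HW": [0.56, 0.53, 0.56, 0.57, 0.02],
    "CC": [0.85, 0.77, 0.79, 0.72, 0.64, 0.60],
    "CBC": [0.76, 0.63, 0.67, 0.67, 0.56, 0.60, 0.76],
    "LMA": [0.67, 0.49, 0.52, 0.61, 0.35, 0.46, 0.64, 0.68],
    "LMD": [0.73, 0.56, 0.59, 0.65, 0.56, 0.46, 0.67, 0.67, 0.83],
    "SFT": [0.62, 0.50, 0.52, 0.53, 0.46, 0.48, 0.60, 0.62, 0.54, 0.53],
}


def _sym_from_triangles(upper: dict, lower: bool = False) -> pd.DataFrame:
    out = pd.DataFrame(np.eye(len(TRAITS)), index=TRAITS, columns=TRAITS)
    for t, row in upper.items():
        i = TRAITS.index(t)
        partners = TRAITS[:i] if lower else TRAITS[i + 1 :]
        for u, v in zip(partners, row):
            out.loc[t, u] = out.loc[u, t] = v
    return out


def genetic_correlation_frame() -> pd.DataFrame:
    """Symmetric matrix of the published genetic correlations."""
    return _sym_from_triangles(_RG_UPPER)


def phenotypic_correlation_frame() -> pd.DataFrame:
    """Symmetric matrix of the published phenotypic correlations."""
    return _sym_from_triangles(_RP_LOWER, lower=True)


GENETIC_CORRELATIONS = genetic_correlation_frame()
PHENOTYPIC_CORRELATIONS = phenotypic_correlation_frame()

#: Published direct (diagonal) and relative correlated responses.
#: Row = auxiliary (selected) trait, column = responding trait.
#: Three cells are internally inconsistent with the published CR formula
#: (see tests): (WH, CC) prints the raw rG 0.7600 instead of 0.8008;
#: (LMD, RH) and (SFT, RH) duplicate the adjacent BL column.
_RESPONSE_ROWS = [
    [9.3278, 0.6486, 0.6638, 0.7136, 0.6610, 0.5452, 0.7711, 0.9239, 41.0328, 0.7914, 0.5117],
    [0.9380, 2.2413, 0.9095, 0.7849, 0.5875, 0.5710, 0.7600, 0.9210, 35.4441, 0.7106, 0.4733],
    [0.9401, 0.8906, 2.4144, 0.7767, 0.6042, 0.5860, 0.8134, 0.9693, 36.4507, 0.7408, 0.4871],
    [0.9422, 0.7166, 0.7242, 2.4614, 0.5614, 0.5759, 0.7249, 0.9359, 41.1729, 0.7760, 0.4884],
    [0.7203, 0.4427, 0.4649, 0.4633, 1.1471, 0.0184, 0.5763, 0.6980, 22.9263, 0.6279, 0.3780],
    [0.7051, 0.5107, 0.5352, 0.5642, 0.0218, 1.3997, 0.5979, 0.8295, 30.2343, 0.5400, 0.4387],
    [1.0043, 0.7212, 0.7480, 0.7151, 0.6887, 0.6021, 3.5951, 1.0266, 42.8704, 0.8068, 0.5300],
    [0.6252, 0.4309, 0.4631, 0.4796, 0.4334, 0.4340, 0.5334, 0.2369, 32.3268, 0.5815, 0.3950],
    [0.0123, 0.0088, 0.0077, 0.0093, 0.0063, 0.0070, 0.0099, 0.0143, 0.0004, 0.0150, 0.0076],
    [0.7108, 0.4413, 0.5279, 0.5279, 0.5175, 0.3750, 0.5564, 0.7719, 44.9132, 0.1266, 0.3954],
    [0.8257, 0.5282, 0.5970, 0.5970, 0.5598, 0.5473, 0.6568, 0.9420, 41.1133, 0.7104, 0.0482],
]

#: Cells of the published response matrix that contradict the published
#: formula (row = selected trait, column = responding trait).
RESPONSE_MATRIX_MISPRINTS = (("WH", "CC"), ("LMD", "RH"), ("SFT", "RH"))


def response_matrix_frame() -> pd.DataFrame:
    """The published response matrix as printed (including misprints)."""
    return pd.DataFrame(_RESPONSE_ROWS, index=TRAITS, columns=TRAITS)


RESPONSE_MATRIX = response_matrix_frame()

#: Published overall least-square means per trait (trait units).
OVERALL_MEANS = pd.Series(
    [175.41, 108.35, 111.85, 103.74, 33.93, 30.56, 135.18, 15.69, 19.36,
     3.086, 0.655],
    index=pd.Index(TRAITS, name="trait"),
)

#: Published least-square-mean contrasts (level minus level) used as
#: simulator fixed-effect defaults: factor -> trait -> full contrast.
#: Sexes: male - female; seasons: spring - summer; dam age: <=6 - >6 yr;
#: birth-weight class: <33 kg minus >=33 kg.
FIXED_EFFECT_CONTRASTS = {
    "sex": {
        "BW": 14.83, "WH": 1.30, "RH": 1.22, "BL": 2.20, "CW": 0.32,
        "HW": 1.88, "CC": 1.77, "CBC": 0.66, "LMA": 0.25, "LMD": 0.125,
        "SFT": -0.017,
    },
    "birth_season": {
        "BW": 3.43, "WH": 0.08, "RH": -0.97, "BL": -0.07, "CW": 3.00,
        "HW": -3.05, "CC": 0.50, "CBC": 0.10, "LMA": -0.23, "LMD": 0.069,
        "SFT": -0.016,
    },
    "dam_age_class": {
        "BW": -0.71, "WH": 0.18, "RH": 0.49, "BL": 0.60, "CW": -0.60,
        "HW": 0.42, "CC": 0.43, "CBC": -0.07, "LMA": -0.93, "LMD": -0.043,
        "SFT": -0.009,
    },
    "birth_weight_class": {
        "BW": -8.03, "WH": -1.34, "RH": -1.47, "BL": -1.06, "CW": -0.88,
        "HW": 0.37, "CC": -2.85, "CBC": -0.22, "LMA": 0.0, "LMD": 0.0,
        "SFT": 0.0,
    },
}

#: Published candidate-SNP genotype counts in this population.
SNP_GENOTYPE_COUNTS = {
    "LCORL-AX-85166825": {"TT": 227, "TC": 9},
    "HMGA2-AX-85179490": {"CC": 162, "TC": 70, "TT": 3},
}
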