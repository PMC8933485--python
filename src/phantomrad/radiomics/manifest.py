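"""Canonical manifest of the 86 extracted features.

The default set comprises 18 first-order statistics, 22 grey level
co-occurrence (GLCM), 14 grey level dependence (GLDM), 16 grey level run
length (GLRLM) and 16 grey level size zone (GLSZM) features, in the fixed
order below.  Two redundant/deprecated GLCM features (the sum average,
which duplicates twice the joint average on a symmetric matrix, and the
maximal correlation coefficient) are excluded to pin the count at 22.
"""

FIRSTORDER_FEATURES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

FAMILIES = (
    ("firstorder", FIRSTORDER_FEATURES),
    ("glcm", GLCM_FEATURES),
    ("gldm", GLDM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
)

#: Canonical ordered names, e.g. ``firstorder_Energy``, ``glcm_Contrast``.
CANONICAL_NAMES = tuple(
    f"{family}_{name}" for family, names in FAMILIES for name in names
)

FAMILY_COUNTS = {family: len(names) for family, names in FAMILIES}

N_FEATURES = len(CANONICAL_NAMES)
assert N_FEATURES == 86


def family_of(feature_name: str) -> str:
    """Family tag of a canonical feature name."""
    family = feature_name.split("_", 1)[0]
    if family not in FAMILY_COUNTS:
        raise KeyError(f"unknown feature {feature_name!r}")
    return family
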