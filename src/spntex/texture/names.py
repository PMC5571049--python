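"""Canonical names of the 59 per-image texture features, in fixed order.

The 59 features comprise 10 histogram features, 8 first-order features,
22 co-occurrence (GLCM) features, 11 run-length (GLRLM) features, 5
neighboring gray-level dependence (NGLDM) features and 3 neighborhood
gray-tone difference (NGTDM) features.  Cohort matrices carry 3 x 59 = 177
columns prefixed ``ePET_``, ``dPET_`` and ``CT_``.

Naming notes: the histogram and first-order families share several
statistic names (mean, skewness, kurtosis, energy, entropy); the histogram
instances carry a ``Hist`` prefix so all 59 names are distinct.  Among the
co-occurrence features, "Inertia" is the standard synonym of Contrast and
is represented once (as ContrastGLCM), and the traditionally duplicated
"Inverse Difference Moment" slot is implemented as InverseDifference
(non-squared denominator), keeping the family at 22 distinct features.
"""

HISTOGRAM_NAMES = [
    "Max",
    "TotalLesionGlycolysis",
    "HistMean",
    "Min",
    "Volume",
    "HistSkewness",
    "HistKurtosis",
    "HistEnergy",
    "HistEntropy",
    "StandardDeviation",
]

FIRST_ORDER_NAMES = [
    "Mean",
    "Median",
    "CoefficientOfVariation",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Entropy",
    "Variance",
]

GLCM_NAMES = [
    "AngularMoment",
    "ContrastGLCM",
    "Correlation",
    "SumOfSquaresVariance",
    "InverseDifferenceMoment",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "EntropyGLCM",
    "DifferenceVariance",
    "DifferenceEntropy",
    "InformationMeasureOfCorrelation1",
    "InformationMeasureOfCorrelation2",
    "MaximalCorrelationCoefficient",
    "MaximumProbability",
    "DiagonalMoment",
    "Dissimilarity",
    "DifferenceEnergy",
    "InverseDifference",
    "SumEnergy",
    "ClusterShade",
    "ClusterProminence",
]

GLRLM_NAMES = [
    "SmallRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonuniformity",
    "RunLengthNonuniformity",
    "RunPercentage",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

NGLDM_NAMES = [
    "SmallNumberEmphasis",
    "LargeNumberEmphasis",
    "NumberNonuniformity",
    "SecondMoment",
    "EntropyNGL",
]

NGTDM_NAMES = [
    "Coarseness",
    "ContrastNGL",
    "Busyness",
]

MATRIX_NAMES = GLCM_NAMES + GLRLM_NAMES + NGLDM_NAMES + NGTDM_NAMES

FEATURE_NAMES = HISTOGRAM_NAMES + FIRST_ORDER_NAMES + MATRIX_NAMES

assert len(FEATURE_NAMES) == 59
assert len(set(FEATURE_NAMES)) == 59

IMAGE_TYPES = ("ePET", "dPET", "CT")

COHORT_COLUMNS = [
    f"{img}_{name}" for img in IMAGE_TYPES for name in FEATURE_NAMES
]

assert len(COHORT_COLUMNS) == 177
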