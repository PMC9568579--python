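"""The 107-feature radiomics catalog.

The catalog mirrors the standard CT radiomics feature set: 18 first-order
statistics, 14 shape descriptors, 24 gray level co-occurrence matrix (GLCM),
16 gray level run length matrix (GLRLM), 16 gray level size zone matrix
(GLSZM), 5 neighbouring gray tone difference matrix (NGTDM) and 14 gray
level dependence matrix (GLDM) features.  Names are prefixed with their
class (``glrlm_GrayLevelNonUniformity``) because several texture classes
reuse the same base name.

Only a small subset is computed natively by this package: the eight
segmentation-robust, uncorrelated features used for heterogeneity profiling
(90th percentile, large dependence emphasis, large dependence high gray
level emphasis, dependence variance, informational measure of correlation 1,
sphericity, maximum 2D diameter in the axial slice, voxel volume) plus mesh
volume for comparison.  The full catalog exists so that externally extracted
feature tables can be validated by name.
"""

from __future__ import annotations

from dataclasses import dataclass

FEATURE_CLASSES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

_FIRSTORDER = [
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median", "Minimum",
    "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
    "TotalEnergy", "Uniformity", "Variance",
]

_SHAPE = [
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
]

_GLCM = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]

_GLRLM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

_GLSZM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]

_NGTDM = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

_GLDM = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

_BY_CLASS = {
    "firstorder": _FIRSTORDER,
    "shape": _SHAPE,
    "glcm": _GLCM,
    "glrlm": _GLRLM,
    "glszm": _GLSZM,
    "ngtdm": _NGTDM,
    "gldm": _GLDM,
}

#: The eight segmentation-robust, uncorrelated features profiled natively.
ROBUST_FEATURES = (
    "firstorder_90Percentile",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_DependenceVariance",
    "glcm_Imc1",
    "shape_Sphericity",
    "shape_Maximum2DDiameterSlice",
    "shape_VoxelVolume",
)

#: Features this package can compute from an image+mask pair (catalog flags).
NATIVE_FEATURES = ROBUST_FEATURES + ("shape_MeshVolume",)


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    feature_class: str
    natively_computed: bool


@dataclass(frozen=True)
class FeatureCatalog:
    entries: tuple[CatalogEntry, ...]

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FEATURE_CLASSES}
        for e in self.entries:
            counts[e.feature_class] += 1
        return counts

    def native_names(self) -> list[str]:
        return [e.name for e in self.entries if e.natively_computed]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)


def catalog() -> FeatureCatalog:
    """Return the fixed 107-entry feature catalog."""
    entries = []
    for cls in FEATURE_CLASSES:
        for base in _BY_CLASS[cls]:
            name = f"{cls}_{base}"
            entries.append(CatalogEntry(name, cls, name in NATIVE_FEATURES))
    return FeatureCatalog(tuple(entries))
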