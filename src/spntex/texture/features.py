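"""Whole-VOI statistics and the 59-feature per-image extraction.

Matrix features (GLCM/GLRLM/NGLDM/NGTDM) are computed per voxel-centred
patch and aggregated to the lesion by the unweighted arithmetic mean over
all in-mask patch centres.  Histogram and first-order features are computed
once on the whole VOI.  Cohort assembly produces the 177-column matrix
(ePET_, dPET_, CT_ prefixes): ePET and CT features use the early-timepoint
mask, dPET features the delayed-timepoint mask.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..types import DualTimeStudy, EmptyVOIError, ImageVolume, PipelineError, VOIMask
from .names import (
    COHORT_COLUMNS,
    FEATURE_NAMES,
    FIRST_ORDER_NAMES,
    HISTOGRAM_NAMES,
    MATRIX_NAMES,
)
from .patches import BinnedVolume, discretize, extract_patches, _patch_vector, Patch

logger = logging.getLogger("spntex.texture")

__all__ = [
    "histogram_features",
    "first_order_features",
    "lesion_features",
    "cohort_feature_matrix",
]


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness and (Pearson) kurtosis.

    Skewness and kurtosis of a zero-variance sample are returned as 0
    (degenerate-case policy; logged by the caller's lesion extraction).
    """
    mean = float(x.mean())
    centred = x - mean
    m2 = float((centred**2).mean())
    if m2 == 0.0:
        return mean, 0.0, 0.0, 0.0
    m3 = float((centred**3).mean())
    m4 = float((centred**4).mean())
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def _binned_probabilities(binned: BinnedVolume, mask: VOIMask) -> np.ndarray:
    counts = np.bincount(binned.bins[mask.voxels], minlength=binned.n_bins + 1)[1:]
    return counts / counts.sum()


def histogram_features(
    volume: ImageVolume, mask: VOIMask, n_bins: int = 256
) -> dict[str, float]:
    """10 histogram features of the whole VOI.

    Max/Min/Mean/SD/skewness/kurtosis are computed on the raw intensity
    distribution; Volume is the metabolic volume in mL, total lesion
    glycolysis (TLG) is mean x volume; energy and entropy come from the
    ``n_bins``-bin normalized histogram (natural log).
    """
    mask.check_aligned(volume)
    if mask.n_voxels == 0:
        raise EmptyVOIError("histogram_features requires a non-empty VOI")
    x = volume.voxels[mask.voxels]
    mean, m2, skew, kurt = _moments(x)
    volume_ml = mask.n_voxels * float(np.prod(mask.spacing_mm)) / 1000.0
    p = _binned_probabilities(discretize(volume, mask, n_bins), mask)
    nz = p[p > 0]
    return {
        "Max": float(x.max()),
        "TotalLesionGlycolysis": mean * volume_ml,
        "HistMean": mean,
        "Min": float(x.min()),
        "Volume": volume_ml,
        "HistSkewness": skew,
        "HistKurtosis": kurt,
        "HistEnergy": float((nz**2).sum()),
        "HistEntropy": float(-(nz * np.log(nz)).sum()),
        "StandardDeviation": float(np.sqrt(m2)),
    }


def first_order_features(
    volume: ImageVolume, mask: VOIMask, n_bins: int = 256
) -> dict[str, float]:
    """8 first-order features on the raw in-VOI intensities.

    Coefficient of variation is SD/mean (0, flagged, when the mean is 0);
    energy is the sum of squared intensities; entropy uses the same
    ``n_bins`` histogram as the histogram family.
    """
    mask.check_aligned(volume)
    if mask.n_voxels == 0:
        raise EmptyVOIError("first_order_features requires a non-empty VOI")
    x = volume.voxels[mask.voxels]
    mean, m2, skew, kurt = _moments(x)
    if mean != 0.0:
        cov = float(np.sqrt(m2)) / mean
    else:
        cov = 0.0
        logger.debug("degenerate CoV (zero mean) returned as 0")
    p = _binned_probabilities(discretize(volume, mask, n_bins), mask)
    nz = p[p > 0]
    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "CoefficientOfVariation": cov,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x**2).sum()),
        "Entropy": float(-(nz * np.log(nz)).sum()),
        "Variance": m2,
    }


def lesion_features(
    volume: ImageVolume,
    mask: VOIMask,
    n_bins: int = 256,
    patch_size: int = 5,
) -> pd.Series:
    """The 59 named features of one image type for one lesion.

    Matrix features are the mean over the per-patch values of all in-mask
    patch centres; whole-VOI families are computed once.  The result is a
    Series indexed by :data:`FEATURE_NAMES`, guaranteed finite.
    """
    values: dict[str, float] = {}
    values.update(histogram_features(volume, mask, n_bins))
    values.update(first_order_features(volume, mask, n_bins))

    binned = discretize(volume, mask, n_bins)
    total = np.zeros(len(MATRIX_NAMES))
    n_patches = 0
    for patch in extract_patches(binned, mask, patch_size):
        total += _patch_vector(patch, n_bins)
        n_patches += 1
    total /= n_patches
    values.update(dict(zip(MATRIX_NAMES, total.tolist())))

    series = pd.Series(values, dtype=float).reindex(FEATURE_NAMES)
    if not np.isfinite(series.to_numpy()).all():
        bad = series.index[~np.isfinite(series.to_numpy())].tolist()
        raise PipelineError(f"non-finite features after extraction: {bad}")
    return series


def cohort_feature_matrix(
    studies: list[DualTimeStudy],
    n_bins: int = 256,
    patch_size: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """177-column feature matrix (rows = lesions) and the label vector.

    ePET and CT features are extracted on the early mask, dPET features on
    the delayed mask.  Extraction failures abort with the lesion id in the
    error message.
    """
    rows = []
    labels = []
    index = []
    for study in studies:
        try:
            parts = {
                "ePET": lesion_features(study.early_pet, study.early_mask, n_bins, patch_size),
                "dPET": lesion_features(study.delayed_pet, study.delayed_mask, n_bins, patch_size),
                "CT": lesion_features(study.ct, study.early_mask, n_bins, patch_size),
            }
        except Exception as err:
            raise PipelineError(f"feature extraction failed for lesion {study.id}: {err}") from err
        row = pd.concat([parts[img].add_prefix(f"{img}_") for img in ("ePET", "dPET", "CT")])
        rows.append(row)
        labels.append(study.label)
        index.append(study.id)
    if not rows:
        matrix = pd.DataFrame(columns=COHORT_COLUMNS, dtype=float)
        return matrix, pd.Series([], dtype=object, name="label")
    matrix = pd.DataFrame(rows, index=index)[COHORT_COLUMNS]
    return matrix, pd.Series(labels, index=index, name="label")
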