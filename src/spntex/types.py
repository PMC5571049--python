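"""Core containers for dual-time-point PET/CT lesion studies.

A study bundles three co-registered 3-D volumes for one solitary pulmonary
nodule (SPN): an early FDG PET scan (~60 min post injection, SUV units), a
delayed FDG PET scan (~180 min, SUV units) and a CT scan (Hounsfield units),
together with a binary volume-of-interest (VOI) mask per PET timepoint.

Axis convention: voxel arrays are indexed ``(axial slice, row, column)``,
0-based, with per-axis voxel spacing recorded in millimetres in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

Modality = Literal["PET", "CT"]
Timepoint = Literal["early", "delayed", "none"]
Units = Literal["SUV", "HU"]
Label = Literal["benign", "malignant", "unknown"]


class SpntexError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SpntexError, ValueError):
    """A parameter violates its documented precondition."""


class AlignmentError(SpntexError):
    """Volume and mask (or two volumes) disagree in shape or spacing."""


class EmptyVOIError(SpntexError):
    """An operation requiring in-mask voxels received an empty mask."""


class DegenerateGeometryError(SpntexError):
    """Requested nodule geometry rasterizes to zero voxels."""


class UndefinedRIError(SpntexError):
    """Retention index is undefined (early SUVmax <= 0)."""


class DegenerateLabelsError(SpntexError):
    """Both classes are required but only one is present."""


class StratificationError(SpntexError):
    """A class has fewer members than the number of folds."""


class DegenerateVarianceError(SpntexError):
    """A variance estimate is zero where a nonzero one is required."""


class PipelineError(SpntexError):
    """A pipeline stage failed; the message carries stage/lesion context."""


def _check_spacing(spacing_mm: np.ndarray) -> np.ndarray:
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise InvalidArgumentError(
            f"voxel spacing must be 3 positive lengths in mm, got {spacing_mm!r}"
        )
    return spacing


@dataclass
class ImageVolume:
    """A 3-D scalar grid with geometry and acquisition metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities; SUV for PET (non-negative), HU for CT.
    spacing_mm : array-like of 3 floats
        Voxel spacing per axis in mm, same axis order as ``voxels``.
    modality : {"PET", "CT"}
    timepoint : {"early", "delayed", "none"}
    units : {"SUV", "HU"}
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    modality: Modality
    timepoint: Timepoint = "none"
    units: Units = "SUV"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise InvalidArgumentError("voxels must be a non-empty 3-D grid")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.modality not in ("PET", "CT"):
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")
        if self.units == "SUV" and np.nanmin(self.voxels) < 0:
            raise InvalidArgumentError("PET volumes in SUV units must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class VOIMask:
    """Binary lesion mask aligned to an :class:`ImageVolume`.

    Values other than {0, 1} are rejected rather than thresholded, so that
    upstream segmentation errors surface instead of being silently binarized.
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        uniques = np.unique(arr)
        if not np.all(np.isin(uniques, (0, 1))):
            raise InvalidArgumentError(
                f"mask values must be exactly 0 or 1, found {uniques[:8]!r}"
            )
        self.voxels = arr.astype(bool)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise InvalidArgumentError("mask must be a non-empty 3-D grid")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.voxels.shape != volume.voxels.shape:
            raise AlignmentError(
                f"mask shape {self.voxels.shape} != volume shape {volume.voxels.shape}"
            )
        if not np.allclose(self.spacing_mm, volume.spacing_mm):
            raise AlignmentError(
                f"mask spacing {self.spacing_mm} != volume spacing {volume.spacing_mm}"
            )


@dataclass
class DualTimeStudy:
    """One lesion: early PET, delayed PET, CT, per-timepoint masks, label."""

    id: str
    early_pet: ImageVolume
    delayed_pet: ImageVolume
    ct: ImageVolume
    early_mask: VOIMask
    delayed_mask: VOIMask
    label: Label = "unknown"
    visual_score: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # ePET and CT live on the early grid; dPET on the delayed grid.
        self.early_mask.check_aligned(self.early_pet)
        self.early_mask.check_aligned(self.ct)
        self.delayed_mask.check_aligned(self.delayed_pet)
        if self.label not in ("benign", "malignant", "unknown"):
            raise InvalidArgumentError(f"unknown label {self.label!r}")
        if self.visual_score is not None:
            score = int(self.visual_score)
            if not 1 <= score <= 5:
                raise InvalidArgumentError(
                    f"visual score must be in 1..5, got {self.visual_score!r}"
                )
            self.visual_score = score
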