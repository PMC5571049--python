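"""Gray-level discretization and voxel-centred patch extraction.

Intensities inside the volume of interest are resampled to ``n_bins``
(default 256) equal-width bins spanning the in-mask [min, max]; bin edges
therefore shift with the data, making every binned matrix feature invariant
to adding a constant to all intensities.  Out-of-mask voxels are binned with
the same edges and clipped into 1..n_bins, because a patch centred near the
VOI boundary legitimately contains background voxels: patch membership
requires only that the CENTER voxel lie inside the VOI, while positions
outside the image carry a validity flag and are excluded from every matrix
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ..types import EmptyVOIError, ImageVolume, InvalidArgumentError, VOIMask
from . import _kernels
from .names import GLCM_NAMES, GLRLM_NAMES, NGLDM_NAMES, NGTDM_NAMES

__all__ = [
    "BinnedVolume",
    "Patch",
    "discretize",
    "extract_patches",
    "patch_matrix_features",
    "glcm_features",
    "glrlm_features",
    "ngldm_features",
    "ngtdm_features",
]


@dataclass
class BinnedVolume:
    """Integer bin grid (1..n_bins for every in-mask voxel) plus edges."""

    bins: np.ndarray
    n_bins: int
    bin_edges: np.ndarray


@dataclass
class Patch:
    """A cube of bin values centred on one in-VOI voxel.

    ``valid`` flags positions that fall inside the image; bins at invalid
    positions are placeholders and never enter any matrix.
    """

    bins: np.ndarray
    valid: np.ndarray
    center_index: tuple[int, int, int]


def discretize(volume: ImageVolume, mask: VOIMask, n_bins: int = 256) -> BinnedVolume:
    """Equal-width discretization of the VOI intensity range.

    The in-mask minimum maps to bin 1 and the in-mask maximum to bin
    ``n_bins``; values equal to an internal bin edge go to the higher bin.
    A constant VOI maps every voxel to bin 1.
    """
    mask.check_aligned(volume)
    if mask.n_voxels == 0:
        raise EmptyVOIError("discretize requires a non-empty VOI")
    if n_bins < 1:
        raise InvalidArgumentError("n_bins must be >= 1")
    in_mask = volume.voxels[mask.voxels]
    vmin = float(in_mask.min())
    vmax = float(in_mask.max())
    edges = np.linspace(vmin, vmax, n_bins + 1)
    if vmax == vmin:
        bins = np.ones(volume.voxels.shape, dtype=np.int64)
    else:
        width = (vmax - vmin) / n_bins
        bins = np.floor((volume.voxels - vmin) / width).astype(np.int64) + 1
        np.clip(bins, 1, n_bins, out=bins)
    return BinnedVolume(bins=bins, n_bins=n_bins, bin_edges=edges)


def extract_patches(
    binned: BinnedVolume, mask: VOIMask, patch_size: int = 5
) -> Iterator[Patch]:
    """Yield one patch per in-mask voxel (`patch_size` must be odd)."""
    if patch_size < 1 or patch_size % 2 == 0:
        raise InvalidArgumentError("patch_size must be a positive odd integer")
    if mask.n_voxels == 0:
        raise EmptyVOIError("extract_patches requires a non-empty VOI")
    half = patch_size // 2
    shape = binned.bins.shape
    centers = np.argwhere(mask.voxels)
    for cz, cy, cx in centers:
        bins = np.ones((patch_size,) * 3, dtype=np.int64)
        valid = np.zeros((patch_size,) * 3, dtype=np.bool_)
        z0, z1 = cz - half, cz + half + 1
        y0, y1 = cy - half, cy + half + 1
        x0, x1 = cx - half, cx + half + 1
        sz0, sy0, sx0 = max(z0, 0), max(y0, 0), max(x0, 0)
        sz1, sy1, sx1 = min(z1, shape[0]), min(y1, shape[1]), min(x1, shape[2])
        dst = (
            slice(sz0 - z0, sz1 - z0),
            slice(sy0 - y0, sy1 - y0),
            slice(sx0 - x0, sx1 - x0),
        )
        bins[dst] = binned.bins[sz0:sz1, sy0:sy1, sx0:sx1]
        valid[dst] = True
        yield Patch(bins=bins, valid=valid, center_index=(int(cz), int(cy), int(cx)))


def _patch_vector(patch: Patch, n_bins: int | None = None) -> np.ndarray:
    if n_bins is None:
        n_bins = int(patch.bins[patch.valid].max()) if patch.valid.any() else 1
    return _kernels.matrix_features_patch(
        np.ascontiguousarray(patch.bins, dtype=np.int64),
        np.ascontiguousarray(patch.valid, dtype=np.bool_),
        n_bins,
        _kernels.OFFSETS,
        _kernels.NEIGHBORS26,
    )


def patch_matrix_features(patch: Patch, n_bins: int | None = None) -> dict[str, float]:
    """All 41 matrix features of one patch as a name -> value mapping."""
    vec = _patch_vector(patch, n_bins)
    names = GLCM_NAMES + GLRLM_NAMES + NGLDM_NAMES + NGTDM_NAMES
    return dict(zip(names, vec.tolist()))


def glcm_features(patch: Patch, n_bins: int | None = None) -> dict[str, float]:
    """22 co-occurrence features averaged over the 12 plane-direction offsets."""
    vec = _patch_vector(patch, n_bins)
    return dict(zip(GLCM_NAMES, vec[: len(GLCM_NAMES)].tolist()))


def glrlm_features(patch: Patch, n_bins: int | None = None) -> dict[str, float]:
    """11 run-length features averaged over the 12 plane-direction offsets."""
    vec = _patch_vector(patch, n_bins)
    a = len(GLCM_NAMES)
    return dict(zip(GLRLM_NAMES, vec[a : a + len(GLRLM_NAMES)].tolist()))


def ngldm_features(patch: Patch, n_bins: int | None = None) -> dict[str, float]:
    """5 gray-level dependence features (26-connected, tolerance 0)."""
    vec = _patch_vector(patch, n_bins)
    a = len(GLCM_NAMES) + len(GLRLM_NAMES)
    return dict(zip(NGLDM_NAMES, vec[a : a + len(NGLDM_NAMES)].tolist()))


def ngtdm_features(patch: Patch, n_bins: int | None = None) -> dict[str, float]:
    """Coarseness, contrast and busyness (26-connected neighborhood)."""
    vec = _patch_vector(patch, n_bins)
    a = len(GLCM_NAMES) + len(GLRLM_NAMES) + len(NGLDM_NAMES)
    return dict(zip(NGTDM_NAMES, vec[a:].tolist()))
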