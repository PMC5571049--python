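"""Reading and writing studies (NIfTI volumes + CSV manifest), metabolic
volume, and the cohort's lesion-size exclusion rule.

Lesions whose early-timepoint metabolic volume is below 5 mL are excluded
before texture analysis: texture features are unreliable on small volumes of
interest.  The exclusion is strict (< 5 mL is removed, exactly 5 mL is kept)
and uses the EARLY mask only.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    AlignmentError,
    DualTimeStudy,
    ImageVolume,
    InvalidArgumentError,
    VOIMask,
)

__all__ = [
    "metabolic_volume",
    "filter_cohort_by_volume",
    "write_study",
    "read_study",
    "write_manifest",
    "read_manifest",
]

MANIFEST_COLUMNS = [
    "id",
    "early_pet",
    "delayed_pet",
    "ct",
    "early_mask",
    "delayed_mask",
    "label",
    "visual_score",
]


def metabolic_volume(mask: VOIMask) -> float:
    """Mask volume in mL: voxel count x voxel volume (mm^3) / 1000."""
    return mask.n_voxels * float(np.prod(mask.spacing_mm)) / 1000.0


def filter_cohort_by_volume(
    studies: Iterable[DualTimeStudy], min_ml: float = 5.0
) -> tuple[list[DualTimeStudy], list[DualTimeStudy]]:
    """Split a cohort into (retained, excluded) by early-mask metabolic volume.

    A study is excluded iff its early-mask volume is strictly below
    ``min_ml``; input order is preserved in both lists.
    """
    retained, excluded = [], []
    for study in studies:
        if metabolic_volume(study.early_mask) < min_ml:
            excluded.append(study)
        else:
            retained.append(study)
    return retained, excluded


def _affine(spacing_mm: np.ndarray) -> np.ndarray:
    # Diagonal affine recording the (slice, row, column) spacing; internal
    # geometry never leaves this convention.
    return np.diag(list(spacing_mm) + [1.0])


def _save_nifti(path: Path, voxels: np.ndarray, spacing_mm: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float32), _affine(spacing_mm))
    img.header.set_zooms(tuple(float(s) for s in spacing_mm))
    nib.save(img, str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    if not Path(path).exists():
        raise IOError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, spacing


def write_study(study: DualTimeStudy, out_dir: Path | str) -> dict:
    """Write one study's five grids as NIfTI files; return its manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    grids = {
        "early_pet": (study.early_pet.voxels, study.early_pet.spacing_mm),
        "delayed_pet": (study.delayed_pet.voxels, study.delayed_pet.spacing_mm),
        "ct": (study.ct.voxels, study.ct.spacing_mm),
        "early_mask": (study.early_mask.voxels.astype(np.uint8), study.early_mask.spacing_mm),
        "delayed_mask": (study.delayed_mask.voxels.astype(np.uint8), study.delayed_mask.spacing_mm),
    }
    for role, (arr, spacing) in grids.items():
        path = out_dir / f"{study.id}_{role}.nii"
        _save_nifti(path, arr, spacing)
        paths[role] = str(path)
    row = {"id": study.id, **paths, "label": study.label,
           "visual_score": study.visual_score if study.visual_score is not None else ""}
    return row


def read_study(manifest_row: Mapping) -> DualTimeStudy:
    """Load one study from a manifest row (dict-like with MANIFEST_COLUMNS).

    Raises an :class:`AlignmentError` when a mask disagrees with its volume
    in shape or spacing, and ``IOError`` for missing files.
    """
    arrays = {}
    spacings = {}
    for role in ("early_pet", "delayed_pet", "ct", "early_mask", "delayed_mask"):
        arrays[role], spacings[role] = _load_nifti(Path(manifest_row[role]))

    score_raw = manifest_row.get("visual_score", "")
    visual_score: Optional[int]
    if score_raw is None or score_raw == "" or (
        isinstance(score_raw, float) and math.isnan(score_raw)
    ):
        visual_score = None
    else:
        visual_score = int(score_raw)

    label = str(manifest_row.get("label", "unknown") or "unknown")
    try:
        return DualTimeStudy(
            id=str(manifest_row["id"]),
            early_pet=ImageVolume(arrays["early_pet"], spacings["early_pet"], "PET", "early", "SUV"),
            delayed_pet=ImageVolume(arrays["delayed_pet"], spacings["delayed_pet"], "PET", "delayed", "SUV"),
            ct=ImageVolume(arrays["ct"], spacings["ct"], "CT", "early", "HU"),
            early_mask=VOIMask(arrays["early_mask"], spacings["early_mask"]),
            delayed_mask=VOIMask(arrays["delayed_mask"], spacings["delayed_mask"]),
            label=label,  # type: ignore[arg-type]
            visual_score=visual_score,
        )
    except InvalidArgumentError:
        raise
    except AlignmentError as err:
        raise AlignmentError(f"study {manifest_row['id']}: {err}") from err


def write_manifest(rows: list[dict], path: Path | str) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: Path | str) -> pd.DataFrame:
    if not Path(path).exists():
        raise IOError(f"manifest not found: {path}")
    return pd.read_csv(path, keep_default_na=False)


def write_cohort(studies: Iterable[DualTimeStudy], out_dir: Path | str) -> Path:
    """Write all studies plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = [write_study(s, out_dir / "volumes") for s in studies]
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    return manifest_path


def read_cohort(manifest_path: Path | str) -> list[DualTimeStudy]:
    df = read_manifest(manifest_path)
    return [read_study(row) for _, row in df.iterrows()]
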