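"""Clinical baseline metrics: SUVmax, retention index, threshold rules.

The retention index (RI) of dual-time-point imaging is the percent change
of SUVmax between the early (~60 min) and delayed (~180 min) scans:

    RI = 100% x (delayed SUVmax - early SUVmax) / early SUVmax

The classic clinical decision rules are early SUVmax > 2.5 and RI > 10% for
malignancy (strict inequalities), and a 5-point visual score read as benign
below 3.5 (i.e. scores 4 and 5 call malignant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .types import (
    DualTimeStudy,
    EmptyVOIError,
    ImageVolume,
    InvalidArgumentError,
    UndefinedRIError,
    VOIMask,
)

__all__ = [
    "suv_max",
    "retention_index",
    "threshold_classify",
    "ClinicalRecord",
    "clinical_record",
    "clinical_table",
    "SUVMAX_THRESHOLD",
    "RI_THRESHOLD",
    "VISUAL_THRESHOLD",
]

SUVMAX_THRESHOLD = 2.5
RI_THRESHOLD = 10.0
VISUAL_THRESHOLD = 3.5


def suv_max(volume: ImageVolume, mask: VOIMask) -> float:
    """Maximum voxel value inside the mask."""
    mask.check_aligned(volume)
    if mask.n_voxels == 0:
        raise EmptyVOIError("SUVmax requires a non-empty VOI")
    return float(volume.voxels[mask.voxels].max())


def retention_index(early_suvmax: float, delayed_suvmax: float) -> float:
    """Percent change of SUVmax from early to delayed scan."""
    if not early_suvmax > 0:
        raise UndefinedRIError(
            f"retention index undefined for early SUVmax {early_suvmax!r}"
        )
    return 100.0 * (delayed_suvmax - early_suvmax) / early_suvmax


def threshold_classify(
    values, threshold: float, rule: Literal["greater", "less"] = "greater"
) -> np.ndarray:
    """Fixed-threshold binary classification (1 = malignant).

    ``greater``: malignant iff value > threshold (strict) — used for SUVmax
    and RI.  ``less``: benign iff value < threshold — used for visual scores,
    where scores >= 3.5 (i.e. 4 or 5) call malignant.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("threshold_classify requires finite values")
    if rule == "greater":
        return (arr > threshold).astype(int)
    if rule == "less":
        return (~(arr < threshold)).astype(int)
    raise InvalidArgumentError(f"unknown rule {rule!r}")


@dataclass
class ClinicalRecord:
    id: str
    early_suvmax: float
    delayed_suvmax: float
    ri_percent: float
    visual_score: Optional[int]
    label: str


def clinical_record(study: DualTimeStudy) -> ClinicalRecord:
    """SUVmax per timepoint (each on its own mask) and retention index."""
    early = suv_max(study.early_pet, study.early_mask)
    delayed = suv_max(study.delayed_pet, study.delayed_mask)
    return ClinicalRecord(
        id=study.id,
        early_suvmax=early,
        delayed_suvmax=delayed,
        ri_percent=retention_index(early, delayed),
        visual_score=study.visual_score,
        label=study.label,
    )


def clinical_table(studies: Iterable[DualTimeStudy]) -> pd.DataFrame:
    """Clinical-metrics table (one row per lesion)."""
    records = [clinical_record(s) for s in studies]
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "early_suvmax": [r.early_suvmax for r in records],
            "delayed_suvmax": [r.delayed_suvmax for r in records],
            "ri_percent": [r.ri_percent for r in records],
            "visual_score": [r.visual_score for r in records],
            "label": [r.label for r in records],
        }
    )
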