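"""Synthetic dual-time-point PET/CT nodule phantoms.

The generator emulates a cohort of solitary pulmonary nodules (SPNs) from a
granuloma-endemic population: malignant nodules and two kinds of benign
nodules — ordinary low-uptake lesions and "granuloma-like" inflammatory
lesions whose early SUVmax exceeds the classic 2.5 malignancy cutoff and
whose FDG retention is high, so that SUVmax and retention index alone are
poor discriminators.  The class signal the downstream texture models are
meant to recover is spatial: malignant uptake is more heterogeneous (shorter
correlation length of a multiplicative Gaussian random field) and gains an
extra independent heterogeneity component on the delayed scan.

Every generated quantity is a pure function of the configuration and its
seed; the realized retention index of each nodule matches its target exactly
(by rescaling), well within the documented +/-1 percentage-point contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    DegenerateGeometryError,
    DualTimeStudy,
    ImageVolume,
    InvalidArgumentError,
    VOIMask,
)

__all__ = [
    "NoduleConfig",
    "ClassDistribution",
    "CohortConfig",
    "gaussian_random_field",
    "make_nodule",
    "make_cohort",
]

#: Multiplicative heterogeneity fields are clipped at this positive floor so
#: uptake never dips to zero inside the lesion.
FIELD_FLOOR = 0.05


def gaussian_random_field(
    shape: Sequence[int],
    corr_length_mm: float,
    spacing_mm: Sequence[float],
    seed: int,
) -> np.ndarray:
    """Stationary zero-mean, unit-variance field with Gaussian autocorrelation.

    The field is white Gaussian noise convolved with a Gaussian kernel on a
    periodic (wrap-around) domain, then normalized by the exact L2 norm of
    the kernel, so the marginal variance is 1 up to sampling error only in
    the noise draw.  The autocorrelation is ``exp(-r^2 / (2 L^2))`` with
    ``L = corr_length_mm`` (the kernel sigma is ``L / sqrt(2)`` per axis,
    converted to voxels through the spacing).

    Parameters
    ----------
    shape : three positive ints
    corr_length_mm : float
        Correlation length L in mm; small values give rough (busy) fields.
    spacing_mm : three positive floats
    seed : int
        Fully determines the draw.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise InvalidArgumentError(f"shape must be 3 positive counts, got {shape!r}")
    if not corr_length_mm > 0:
        raise InvalidArgumentError("corr_length_mm must be > 0")
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise InvalidArgumentError("spacing_mm must be 3 positive lengths")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    sigma_vox = (corr_length_mm / math.sqrt(2.0)) / spacing
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    # Exact normalization: response to a unit impulse gives the kernel, whose
    # L2 norm is the output standard deviation under unit white noise.
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
    norm = math.sqrt(float(np.sum(kernel**2)))
    return smooth / norm


@dataclass
class NoduleConfig:
    """Parameters of one synthetic nodule.

    ``early_suvmax_range`` is the interval the nodule's early SUVmax is drawn
    from; ``target_ri_percent`` is the retention index (percent change of
    SUVmax from the early to the delayed scan) the delayed image is scaled to
    realize.  ``heterogeneity_corr_length_mm`` controls texture coarseness
    (small = heterogeneous); ``delayed_extra_amplitude`` adds an independent
    low-amplitude field to the delayed image only (used for malignant
    lesions, so delayed-image texture carries extra class signal).
    """

    diameter_mm: float
    voxel_spacing_mm: Sequence[float] = (4.25, 3.91, 3.91)
    early_suvmax_range: tuple[float, float] = (3.0, 10.0)
    target_ri_percent: float = 20.0
    heterogeneity_corr_length_mm: float = 6.0
    background_suv: float = 0.4
    ct_mean_hu: float = 30.0
    ct_noise_sd_hu: float = 25.0
    seed: int = 0
    heterogeneity_amplitude: float = 0.25
    delayed_extra_amplitude: float = 0.0
    axis_ratio_jitter: float = 0.15
    background_noise_sd_suv: float = 0.05
    ct_background_hu: float = -780.0
    ct_background_sd_hu: float = 40.0
    erode_delayed_mask: bool = False

    def validate(self) -> None:
        if not self.diameter_mm > 0:
            raise InvalidArgumentError("diameter_mm must be > 0")
        spacing = np.asarray(self.voxel_spacing_mm, dtype=float)
        if spacing.shape != (3,) or not np.all(spacing > 0):
            raise InvalidArgumentError("voxel_spacing_mm must be 3 positive lengths")
        lo, hi = self.early_suvmax_range
        if not (self.background_suv < lo <= hi):
            raise InvalidArgumentError(
                "early_suvmax_range lower bound must exceed background_suv"
            )
        if not self.heterogeneity_corr_length_mm > 0:
            raise InvalidArgumentError("heterogeneity_corr_length_mm must be > 0")
        if not 0 <= self.axis_ratio_jitter < 1:
            raise InvalidArgumentError("axis_ratio_jitter must be in [0, 1)")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    radii_mm: np.ndarray,
    spacing: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean ellipsoid mask centred on the grid, plus normalized radius."""
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * sp for n, sp in zip(shape, spacing)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    r2 = (zz / radii_mm[0]) ** 2 + (yy / radii_mm[1]) ** 2 + (xx / radii_mm[2]) ** 2
    return r2 <= 1.0, np.sqrt(r2)


def make_nodule(config: NoduleConfig, *, lesion_id: str = "lesion") -> DualTimeStudy:
    """Rasterize one dual-time PET/CT nodule phantom from its configuration.

    The early PET inside the mask is a smooth radial uptake profile times a
    clipped multiplicative correlated Gaussian field, affinely rescaled so
    the in-mask maximum equals the sampled early SUVmax.  The delayed PET
    reuses the same spatial field (plus an optional independent extra field)
    and is rescaled so the realized retention index equals
    ``target_ri_percent`` exactly.  The CT is mean HU plus white noise inside
    the mask over a lung-like background.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    spacing = np.asarray(config.voxel_spacing_mm, dtype=float)

    # Grid: nodule extent plus a 4-voxel margin per side (room for the 5^3
    # texture patches to stay inside the image).
    margin = 4
    half_extent_vox = np.ceil((config.diameter_mm / 2.0) / spacing).astype(int)
    shape = tuple(int(2 * (h + margin) + 1) for h in half_extent_vox)

    # Ellipsoid radii with volume-preserving axis-ratio jitter.
    base_r = config.diameter_mm / 2.0
    jitter = 1.0 + config.axis_ratio_jitter * rng.uniform(-1.0, 1.0, size=3)
    jitter /= np.prod(jitter) ** (1.0 / 3.0)
    radii = base_r * jitter
    mask, rnorm = _ellipsoid_mask(shape, radii, spacing)
    # A grid-centred ellipsoid always captures the central voxel; anything
    # rasterizing to a single voxel has no usable geometry.
    if mask.sum() <= 1:
        raise DegenerateGeometryError(
            f"diameter {config.diameter_mm} mm rasterizes to zero voxels "
            f"at spacing {spacing.tolist()} mm"
        )

    target_max = float(rng.uniform(*config.early_suvmax_range))
    field_seed = int(rng.integers(0, 2**31 - 1))
    het = gaussian_random_field(
        shape, config.heterogeneity_corr_length_mm, spacing, field_seed
    )
    mult = np.maximum(1.0 + config.heterogeneity_amplitude * het, FIELD_FLOOR)

    profile = 1.0 - 0.5 * np.minimum(rnorm, 1.0) ** 2  # centre 1.0 -> rim 0.5
    raw = profile * mult

    early = np.full(shape, config.background_suv)
    early += rng.normal(0.0, config.background_noise_sd_suv, size=shape)
    # Pin the in-mask maximum of the raw uptake pattern to target_max.
    in_raw = raw[mask]
    scale = (target_max - config.background_suv) / in_raw.max()
    early[mask] = config.background_suv + raw[mask] * scale
    early = np.maximum(early, 0.0)

    # Delayed image: same spatial pattern, optional independent extra field,
    # rescaled so SUVmax hits early_max * (1 + RI/100) exactly.
    delayed = np.full(shape, config.background_suv)
    delayed += rng.normal(0.0, config.background_noise_sd_suv, size=shape)
    dpattern = raw.copy()
    if config.delayed_extra_amplitude > 0:
        extra_seed = int(rng.integers(0, 2**31 - 1))
        extra = gaussian_random_field(
            shape, config.heterogeneity_corr_length_mm, spacing, extra_seed
        )
        dpattern *= np.maximum(
            1.0 + config.delayed_extra_amplitude * extra, FIELD_FLOOR
        )

    early_mask_arr = mask
    delayed_mask_arr = mask
    if config.erode_delayed_mask:
        eroded = ndimage.binary_erosion(mask)
        if eroded.any():
            delayed_mask_arr = eroded

    early_max = float(early[early_mask_arr].max())
    delayed_target = early_max * (1.0 + config.target_ri_percent / 100.0)
    delayed_target = max(delayed_target, config.background_suv * 1.05)
    dscale = (delayed_target - config.background_suv) / dpattern[delayed_mask_arr].max()
    delayed[mask] = config.background_suv + dpattern[mask] * dscale
    delayed = np.maximum(delayed, 0.0)

    ct = rng.normal(config.ct_background_hu, config.ct_background_sd_hu, size=shape)
    ct[mask] = rng.normal(config.ct_mean_hu, config.ct_noise_sd_hu, size=int(mask.sum()))

    return DualTimeStudy(
        id=lesion_id,
        early_pet=ImageVolume(early, spacing, "PET", "early", "SUV"),
        delayed_pet=ImageVolume(delayed, spacing, "PET", "delayed", "SUV"),
        ct=ImageVolume(ct, spacing, "CT", "early", "HU"),
        early_mask=VOIMask(early_mask_arr.astype(np.uint8), spacing),
        delayed_mask=VOIMask(delayed_mask_arr.astype(np.uint8), spacing),
        meta={
            "target_ri_percent": config.target_ri_percent,
            "target_early_suvmax": target_max,
            "diameter_mm": config.diameter_mm,
            "heterogeneity_corr_length_mm": config.heterogeneity_corr_length_mm,
        },
    )


@dataclass
class ClassDistribution:
    """Class-conditional sampling ranges for nodule parameters.

    Diameter, early SUVmax and correlation length are drawn uniformly from
    their intervals; the target retention index is normal (clipped) and the
    CT mean HU is normal.  ``score_probs`` is the distribution of the
    simulated 5-point visual-interpretation score for this class (a noisy
    monotone surrogate for human readers).
    """

    diameter_mm: tuple[float, float]
    early_suvmax: tuple[float, float]
    ri_mean: float
    ri_sd: float
    corr_length_mm: tuple[float, float]
    ct_mean_hu: tuple[float, float]  # (mean, sd)
    delayed_extra_amplitude: float
    score_probs: tuple[float, float, float, float, float]

    def sample(self, rng: np.random.Generator, base: NoduleConfig) -> NoduleConfig:
        ri = float(np.clip(rng.normal(self.ri_mean, self.ri_sd), -60.0, 150.0))
        return replace(
            base,
            diameter_mm=float(rng.uniform(*self.diameter_mm)),
            early_suvmax_range=self.early_suvmax,
            target_ri_percent=ri,
            heterogeneity_corr_length_mm=float(rng.uniform(*self.corr_length_mm)),
            ct_mean_hu=float(rng.normal(*self.ct_mean_hu)),
            delayed_extra_amplitude=self.delayed_extra_amplitude,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


_MALIGNANT = ClassDistribution(
    diameter_mm=(23.0, 30.0),
    early_suvmax=(3.0, 10.0),
    ri_mean=22.0,
    ri_sd=12.0,
    corr_length_mm=(4.0, 7.0),
    ct_mean_hu=(30.0, 15.0),
    delayed_extra_amplitude=0.15,
    score_probs=(0.01, 0.02, 0.03, 0.34, 0.60),
)

_BENIGN = ClassDistribution(
    diameter_mm=(23.0, 30.0),
    early_suvmax=(0.8, 2.4),
    ri_mean=0.0,
    ri_sd=10.0,
    corr_length_mm=(8.0, 14.0),
    ct_mean_hu=(45.0, 25.0),
    delayed_extra_amplitude=0.0,
    score_probs=(0.40, 0.30, 0.16, 0.10, 0.04),
)

# Granuloma-like benign lesions: early SUVmax above the 2.5 cutoff and high
# retention, as seen for active inflammation in endemic regions; spatially
# they remain smoother than malignant lesions.
_GRANULOMA = ClassDistribution(
    diameter_mm=(23.0, 30.0),
    early_suvmax=(3.0, 9.0),
    ri_mean=18.0,
    ri_sd=12.0,
    corr_length_mm=(8.0, 14.0),
    ct_mean_hu=(45.0, 25.0),
    delayed_extra_amplitude=0.0,
    score_probs=(0.10, 0.15, 0.16, 0.44, 0.15),
)


@dataclass
class CohortConfig:
    """Cohort-level configuration: class sizes and per-class distributions.

    Defaults mirror the study conditions of the analysis this package
    implements: 63 malignant and 22 benign lesions, with half of the benign
    lesions granuloma-like (early SUVmax forced above 2.5).
    """

    n_malignant: int = 63
    n_benign: int = 22
    granuloma_fraction: float = 0.5
    malignant: ClassDistribution = field(default_factory=lambda: _MALIGNANT)
    benign: ClassDistribution = field(default_factory=lambda: _BENIGN)
    granuloma: ClassDistribution = field(default_factory=lambda: _GRANULOMA)
    base: NoduleConfig = field(default_factory=lambda: NoduleConfig(diameter_mm=26.0))
    seed: int = 0

    def validate(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise InvalidArgumentError("class counts must be >= 0")
        if not 0.0 <= self.granuloma_fraction <= 1.0:
            raise InvalidArgumentError("granuloma_fraction must be in [0, 1]")


def _sample_score(rng: np.random.Generator, probs: Sequence[float]) -> int:
    p = np.asarray(probs, dtype=float)
    return int(rng.choice(5, p=p / p.sum()) + 1)


def make_cohort(config: CohortConfig) -> list[DualTimeStudy]:
    """Generate the labelled synthetic cohort.

    Returns exactly ``n_malignant + n_benign`` studies (malignant first),
    with ``ceil(granuloma_fraction * n_benign)`` of the benign lesions drawn
    from the granuloma-like distribution.  Reproducible given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    studies: list[DualTimeStudy] = []

    n_granuloma = math.ceil(config.granuloma_fraction * config.n_benign)
    plan: list[tuple[str, ClassDistribution]] = []
    plan += [("malignant", config.malignant)] * config.n_malignant
    plan += [("benign", config.granuloma)] * n_granuloma
    plan += [("benign", config.benign)] * (config.n_benign - n_granuloma)

    for i, (label, dist) in enumerate(plan):
        ncfg = dist.sample(rng, config.base)
        study = make_nodule(ncfg, lesion_id=f"SPN{i:03d}")
        study.label = label  # type: ignore[assignment]
        study.visual_score = _sample_score(rng, dist.score_probs)
        study.meta["class_distribution"] = (
            "malignant" if label == "malignant"
            else ("granuloma" if dist is config.granuloma else "benign")
        )
        studies.append(study)
    return studies
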