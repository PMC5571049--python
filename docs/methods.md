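# Methods

This note documents the models, conventions and design choices behind
`spntex`, in the order the pipeline runs them.

## Synthetic dual-time nodule phantoms

No public image cohort exists for this analysis, so the package ships a
generator whose defaults define the study conditions everything else is
tested under.

**Geometry.** Each nodule is an ellipsoid of the requested diameter
(volume-preserving axis-ratio jitter up to ±15%) rasterized on a grid with
PET-like spacing, default (4.25, 3.91, 3.91) mm, with a 4-voxel margin so
5×5×5 patches around boundary voxels stay inside the image. Default
diameters of 23–30 mm give metabolic volumes of roughly 6–14 mL, all above
the 5 mL exclusion threshold.

**Uptake model.** Early-PET uptake inside the mask is a smooth radial
profile (centre 1.0, rim 0.5) multiplied by a clipped correlated Gaussian
field `max(1 + a·G, 0.05)`; the product is affinely rescaled so the in-mask
maximum equals the nodule's sampled early SUVmax. `G` is white noise
convolved with a Gaussian kernel on a periodic domain and normalized by the
exact kernel L2 norm, giving unit marginal variance and autocorrelation
`exp(-r²/2L²)`; the correlation length `L` is the single heterogeneity
dial (small L = rough). Amplitude `a` defaults to 0.25. The delayed image
reuses the same spatial pattern — malignant lesions additionally receive an
independent low-amplitude (0.15) field, so delayed-image texture carries
extra class signal — and is rescaled so the realized retention index equals
the target exactly (well inside the ±1 percentage-point contract). CT is
mean HU plus white noise inside the mask over a lung-like background
(−780 ± 40 HU); CT carries only a weak class signal (mean-HU overlap), by
design the least informative image type.

**Class-conditional defaults** (chosen once as plausible for a
granuloma-endemic referral population; they are *not* estimates of any
clinical cohort):

| parameter | malignant | benign (granuloma-like) | benign (other) |
|---|---|---|---|
| early SUVmax | U(3, 10) | U(3, 9) | U(0.8, 2.4) |
| target RI (%) | N(22, 12) | N(18, 12) | N(0, 10) |
| correlation length (mm) | U(4, 7) | U(8, 14) | U(8, 14) |
| delayed extra amplitude | 0.15 | 0 | 0 |
| CT mean (HU) | N(30, 15) | N(45, 25) | N(45, 25) |

The default cohort is 63 malignant / 22 benign with half of the benign
lesions granuloma-like, so early SUVmax > 2.5 keeps near-perfect
sensitivity but only ~0.5 specificity, and RI separates the classes poorly
— the failure mode of SUV-based reading in endemic regions. Visual scores
are drawn from class-conditional distributions over the 1–5 scale (a noisy
monotone surrogate for human readers; no image content is read).

**What the generator does not emulate:** scanner physics (PSF, attenuation,
reconstruction artifacts), respiratory motion, lobulated or spiculated
shapes, multi-lesion patients, and reader behaviour beyond the score
distributions. Passing tests therefore demonstrate that the *pipeline*
recovers planted class structure under realistic sizes and noise — not
clinical performance.

## Volume filter and clinical metrics

A lesion is excluded iff its **early-mask** metabolic volume (voxel count ×
voxel volume) is strictly below 5 mL; the delayed mask is never used for
filtering. SUVmax is taken per timepoint on that timepoint's own mask;
RI = 100·(delayed − early)/early requires early SUVmax > 0. The fixed
rules use strict inequalities (SUVmax > 2.5, RI > 10%); visual scores of 4
or 5 (≥ 3.5) call malignant. Ties at a printed threshold are measure-zero
for continuous metrics.

## Texture extraction

**Discretization.** In-mask intensities are resampled to 256 equal-width
bins spanning the in-mask [min, max]; min maps to bin 1, max to bin 256,
values on an internal edge go to the higher bin, and a constant VOI maps to
bin 1 everywhere. Out-of-mask voxels are binned with the same edges and
clipped into range, because patches legitimately include background.
CT uses the same VOI-relative scheme (no fixed HU windowing): one
extraction methodology for all three image types. Bin edges move with the
data, so all binned features are invariant to global intensity shifts.

**Patches.** One 5×5×5 patch per VOI voxel, centred on it. Patch
membership requires only the centre to be in the VOI; voxels outside the
image are flagged invalid and excluded from all matrix counts (a corner
centre retains 27 valid voxels).

**Directional scheme.** GLCM and GLRLM use 4 in-plane distance-1 offsets
(0°, 45°, 90°, 135°) in each of the three orthogonal planes — 12
plane-direction combinations whose multiset is closed under axis
permutation (the three axis offsets each appear in two planes). *Features*,
not matrices, are averaged over combinations. NGLDM and NGTDM use the full
26-connected neighborhood, which is how "all nearest neighbors" enters the
3-D extraction. Co-occurrence matrices are symmetric and normalized per
direction; a direction with no valid pairs is skipped from the GLCM mean.

**The 59 names.** 10 histogram features (Max, TLG, mean, Min, volume,
skewness, kurtosis, 256-bin energy and entropy, SD), 8 first-order features
(mean, median, CoV, skewness, kurtosis, energy = Σx², entropy, variance),
22 GLCM, 11 GLRLM, 5 NGLDM, 3 NGTDM. Histogram and first-order families
share several statistic names; the histogram instances carry a `Hist`
prefix so all 59 columns are distinct. Two naming resolutions in the GLCM
family: *Inertia* is the standard synonym of *Contrast* and is represented
once, and the traditionally duplicated *Inverse Difference Moment* slot is
implemented as *Inverse Difference* (non-squared denominator), keeping the
family at 22 distinct features. Features without a universal formula use
the standard Haralick-family definitions, documented in code:
*Angular Moment* = Σp² (angular second moment), *Sum/Difference Energy* =
Σp²(k) of the sum/difference distributions, *Diagonal Moment* =
Σ p·|i−j|·(i+j)/2. All entropies use the natural logarithm. Gray levels
enter formulas through their actual bin values, not compact indices.

**Degenerate-case policy.** Formulas that divide by zero on constant input
(correlation, CoV, skewness/kurtosis, information measures, busyness)
return 0; coarseness returns 1/ε with ε = 10⁻⁶. This keeps feature vectors
finite for the classifier without inventing texture; occurrences are logged.

**Aggregation.** Matrix features are averaged (unweighted mean) over all
in-mask patch centres; histogram and first-order families are computed once
on the whole VOI. Per lesion and image type this yields exactly 59 finite
values; ePET and CT use the early mask, dPET the delayed mask; the cohort
matrix has 177 named columns.

**Numerics.** The per-patch kernels are numba-compiled. The maximal
correlation coefficient is computed as the second-largest |eigenvalue| of
the symmetrized transition matrix D^(−1/2) P D^(−1/2), which shares its
squared spectrum with the classic Q matrix but is symmetric, so a stable
`eigvalsh` applies; values are clipped to [0, 1]. All 41 matrix features
match independent brute-force enumeration oracles to 1e-10 relative
tolerance in the test suite.

## Feature selection

Classic SFFS with a hard cap of five features: forward steps add the
candidate maximizing the criterion (ties → lowest column index), floating
backward steps remove a feature while removal strictly improves the best
recorded score at the smaller size (strictness plus a visited-subset cache
prevents add/remove cycles). The returned set is the best-scoring subset
found at any size ≤ 5 (ties → smaller subset). The criterion is the mean
accuracy of the downstream linear SVM under an internal stratified 5-fold
cross-validation of the training rows — a wrapper matched to the classifier
actually used, since no selection objective is canonical here. Features are
standardized with training-row statistics before selection and
classification (margin classifiers need comparable scales).

## Models and evaluation

Outer cross-validation is a stratified, seeded 5-fold split (with 22 benign
lesions an unstratified split can lose a class from a fold). Per fold:
standardize on training rows, run SFFS on the feature-set's columns, fit
`SVC(kernel="linear", C=1)`, score held-out rows with the margin decision
value. The five feature sets are eCT, ePET, ePET/CT, dPET and edPET/CT.

Out-of-fold scores are **pooled into one ROC per model** — whole-cohort
confusion counts only make sense for pooled scores — and the mean of
per-fold AUCs is reported alongside as a secondary statistic. Pooled scores
are used raw (no cross-fold calibration); per-fold standardization keeps
them comparable. AUC is the tie-corrected rank-sum probability, identical
to the O(n²) pair-counting estimate. DeLong's structural-components test
compares paired AUCs (identical scores → p = 1 by convention; zero variance
with a nonzero difference is an error, not a p-value). The operating point
minimizing √((1−sens)² + (1−spec)²) is the optimal threshold, ties resolved
toward higher sensitivity. Clinical baselines (early SUVmax, RI, visual
score) are evaluated on the full cohort as single fixed metrics, without
cross-validation. Reported proportions are rounded half-up to two decimals;
AUC confidence intervals use the single-curve DeLong variance.

## Problem sizes

The default cohort (85 lesions × 3 image types, ~140 VOI voxels each)
extracts in about a minute on one CPU; a full five-model run takes about
two minutes. Tests use smaller cohorts (15–30 lesions) for structural
checks and the full default cohort once for the model-ordering check.

## Known limitations

- At 256 bins on ~140-voxel lesions almost every voxel occupies its own
  bin, so run-length and dependence families saturate (runs of length 1,
  dependence 0) and carry little signal; the co-occurrence, NGTDM and
  first-order dispersion features do the discriminative work. This mirrors
  the general caution against fine discretization on small VOIs.
- Patch neighborhoods around the lesion rim include background voxels, so
  rim contrast contributes to every matrix family; phantom classes are
  matched in geometry, so this does not leak label information here, but on
  real data it couples texture features to segmentation style.
- The synthetic effect sizes (SUV, RI and heterogeneity separations) are
  free parameters of the generator, not estimates; absolute AUCs on the
  synthetic cohort exceed what heterogeneous clinical data would give, and
  only orderings between models are meaningful.
- DeLong variance, not bootstrap, is the only interval machinery; nested
  hyperparameter tuning, non-linear kernels and probability calibration are
  out of scope.
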