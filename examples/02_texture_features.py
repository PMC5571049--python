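"""Extract the 59 texture features of one nodule and compare two heterogeneity levels.

Phantoms share geometry, SUVmax (fixed at 6.0) and retention index but
differ in the correlation length of their uptake field: 4 mm (rough,
tumour-like) versus 12 mm (smooth, granuloma-like).  Averaging over a few
seeds shows the systematic texture response: rough uptake raises busyness
and lowers the co-occurrence correlation and coefficient of variation
responds too, while intensity features (Max) stay matched by construction.
"""

import numpy as np

from spntex import NoduleConfig, lesion_features, make_nodule

NAMES = ["Busyness", "Correlation", "ContrastNGL", "CoefficientOfVariation", "Max"]

for corr_mm in (4.0, 12.0):
    means = {n: [] for n in NAMES}
    for seed in range(3):
        study = make_nodule(
            NoduleConfig(
                diameter_mm=26.0,
                heterogeneity_corr_length_mm=corr_mm,
                early_suvmax_range=(6.0, 6.0),
                target_ri_percent=20.0,
                seed=seed,
            ),
        )
        fv = lesion_features(study.early_pet, study.early_mask)  # 59 named features
        for n in NAMES:
            means[n].append(fv[n])
    vals = {n: float(np.mean(v)) for n, v in means.items()}
    print(
        f"correlation length {corr_mm:4.1f} mm: "
        f"Busyness={vals['Busyness']:.3f}  Correlation={vals['Correlation']:.3f}  "
        f"ContrastNGL={vals['ContrastNGL']:.1f}  CoV={vals['CoefficientOfVariation']:.3f}  "
        f"Max={vals['Max']:.2f}"
    )

print("\nShorter correlation length (rougher uptake) -> higher busyness, lower"
      "\nco-occurrence correlation; SUVmax is matched, so only texture differs.")
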