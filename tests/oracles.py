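"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration over voxels, pairs, lines
and neighborhoods — deliberately naive and structurally unrelated to the
package's kernels — so that agreement is evidence of correctness rather
than of shared code.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict

import numpy as np

# The documented directional scheme: 4 in-plane offsets per orthogonal plane.
OFFSETS_12 = [
    (0, 0, 1), (0, 1, 1), (0, 1, 0), (0, 1, -1),
    (0, 0, 1), (1, 0, 1), (1, 0, 0), (1, 0, -1),
    (0, 1, 0), (1, 1, 0), (1, 0, 0), (1, -1, 0),
]

NB26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _in(shape, z, y, x):
    return 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]


def glcm_oracle(bins: np.ndarray, valid: np.ndarray) -> dict[str, float]:
    """22 co-occurrence features by direct pair enumeration, averaged."""
    shape = bins.shape
    per_dir: dict[str, list[float]] = defaultdict(list)
    for off in OFFSETS_12:
        cnt: Counter = Counter()
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not valid[z, y, x]:
                        continue
                    z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                    if _in(shape, z2, y2, x2) and valid[z2, y2, x2]:
                        a, b = int(bins[z, y, x]), int(bins[z2, y2, x2])
                        cnt[(a, b)] += 1
                        cnt[(b, a)] += 1
        if not cnt:
            continue
        total = sum(cnt.values())
        P = {k: v / total for k, v in cnt.items()}
        px: dict[int, float] = defaultdict(float)
        for (i, j), p in P.items():
            px[i] += p
        mu = sum(i * p for i, p in px.items())
        var = sum((i - mu) ** 2 * p for i, p in px.items())

        psum: dict[int, float] = defaultdict(float)
        pdiff: dict[int, float] = defaultdict(float)
        for (i, j), p in P.items():
            psum[i + j] += p
            pdiff[abs(i - j)] += p

        f: dict[str, float] = {}
        f["AngularMoment"] = sum(p * p for p in P.values())
        f["ContrastGLCM"] = sum(p * (i - j) ** 2 for (i, j), p in P.items())
        f["Correlation"] = (
            (sum(p * i * j for (i, j), p in P.items()) - mu * mu) / var
            if var > 0 else 0.0
        )
        f["SumOfSquaresVariance"] = sum(p * (i - mu) ** 2 for (i, j), p in P.items())
        f["InverseDifferenceMoment"] = sum(
            p / (1 + (i - j) ** 2) for (i, j), p in P.items()
        )
        sa = sum(k * q for k, q in psum.items())
        f["SumAverage"] = sa
        f["SumVariance"] = sum((k - sa) ** 2 * q for k, q in psum.items())
        f["SumEntropy"] = -sum(q * math.log(q) for q in psum.values() if q > 0)
        ent = -sum(p * math.log(p) for p in P.values())
        f["EntropyGLCM"] = ent
        da = sum(k * q for k, q in pdiff.items())
        f["DifferenceVariance"] = sum((k - da) ** 2 * q for k, q in pdiff.items())
        f["DifferenceEntropy"] = -sum(q * math.log(q) for q in pdiff.values() if q > 0)
        hx = -sum(p * math.log(p) for p in px.values() if p > 0)
        hxy1 = -sum(
            p * math.log(px[i] * px[j]) for (i, j), p in P.items()
        )
        hxy2 = -sum(
            px[i] * px[j] * math.log(px[i] * px[j])
            for i in px for j in px
        )
        f["InformationMeasureOfCorrelation1"] = (ent - hxy1) / hx if hx > 0 else 0.0
        arg = 1.0 - math.exp(-2.0 * (hxy2 - ent))
        f["InformationMeasureOfCorrelation2"] = math.sqrt(arg) if arg > 0 else 0.0

        levels = sorted(px)
        if len(levels) < 2:
            f["MaximalCorrelationCoefficient"] = 0.0
        else:
            Pm = np.zeros((len(levels), len(levels)))
            for ai, i in enumerate(levels):
                for bi, j in enumerate(levels):
                    Pm[ai, bi] = P.get((i, j), 0.0)
            pxv = Pm.sum(axis=1)
            pyv = Pm.sum(axis=0)
            Q = np.zeros_like(Pm)
            for ai in range(len(levels)):
                for bi in range(len(levels)):
                    Q[ai, bi] = sum(
                        Pm[ai, k] * Pm[bi, k] / (pxv[ai] * pyv[k])
                        for k in range(len(levels))
                    )
            eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
            f["MaximalCorrelationCoefficient"] = min(
                math.sqrt(max(eig[1], 0.0)), 1.0
            )

        f["MaximumProbability"] = max(P.values())
        f["DiagonalMoment"] = sum(
            p * abs(i - j) * (i + j) / 2 for (i, j), p in P.items()
        )
        f["Dissimilarity"] = sum(p * abs(i - j) for (i, j), p in P.items())
        f["DifferenceEnergy"] = sum(q * q for q in pdiff.values())
        f["InverseDifference"] = sum(p / (1 + abs(i - j)) for (i, j), p in P.items())
        f["SumEnergy"] = sum(q * q for q in psum.values())
        f["ClusterShade"] = sum(p * (i + j - 2 * mu) ** 3 for (i, j), p in P.items())
        f["ClusterProminence"] = sum(p * (i + j - 2 * mu) ** 4 for (i, j), p in P.items())
        for k, v in f.items():
            per_dir[k].append(v)
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


def glrlm_oracle(bins: np.ndarray, valid: np.ndarray) -> dict[str, float]:
    """11 run-length features by explicit line/run enumeration, averaged."""
    shape = bins.shape
    n_valid = int(valid.sum())
    per_dir: dict[str, list[float]] = defaultdict(list)
    for off in OFFSETS_12:
        runs: Counter = Counter()  # (gray, length) -> count
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if _in(shape, z - off[0], y - off[1], x - off[2]):
                        continue  # not a line start
                    line = []
                    cz, cy, cx = z, y, x
                    while _in(shape, cz, cy, cx):
                        line.append(
                            int(bins[cz, cy, cx]) if valid[cz, cy, cx] else None
                        )
                        cz += off[0]
                        cy += off[1]
                        cx += off[2]
                    length = 0
                    gray = None
                    for cell in line + [None]:
                        if cell is not None and cell == gray:
                            length += 1
                        else:
                            if gray is not None and length > 0:
                                runs[(gray, length)] += 1
                            gray = cell
                            length = 1 if cell is not None else 0
        nr = sum(runs.values())
        if nr == 0:
            continue
        rg: dict[int, int] = defaultdict(int)
        rl: dict[int, int] = defaultdict(int)
        for (g, l), c in runs.items():
            rg[g] += c
            rl[l] += c
        f = {
            "SmallRunEmphasis": sum(c / l**2 for (g, l), c in runs.items()) / nr,
            "LongRunEmphasis": sum(c * l**2 for (g, l), c in runs.items()) / nr,
            "GrayLevelNonuniformity": sum(c**2 for c in rg.values()) / nr,
            "RunLengthNonuniformity": sum(c**2 for c in rl.values()) / nr,
            "RunPercentage": nr / n_valid,
            "LowGrayLevelEmphasis": sum(c / g**2 for (g, l), c in runs.items()) / nr,
            "HighGrayLevelEmphasis": sum(c * g**2 for (g, l), c in runs.items()) / nr,
            "ShortRunLowGrayLevelEmphasis": sum(
                c / (g**2 * l**2) for (g, l), c in runs.items()
            ) / nr,
            "ShortRunHighGrayLevelEmphasis": sum(
                c * g**2 / l**2 for (g, l), c in runs.items()
            ) / nr,
            "LongRunLowGrayLevelEmphasis": sum(
                c * l**2 / g**2 for (g, l), c in runs.items()
            ) / nr,
            "LongRunHighGrayLevelEmphasis": sum(
                c * g**2 * l**2 for (g, l), c in runs.items()
            ) / nr,
        }
        for k, v in f.items():
            per_dir[k].append(v)
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


def ngldm_oracle(bins: np.ndarray, valid: np.ndarray) -> dict[str, float]:
    """5 dependence features by direct neighborhood counting."""
    shape = bins.shape
    deps: Counter = Counter()  # (gray, dependence) -> count
    n = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not valid[z, y, x]:
                    continue
                dep = 0
                for off in NB26:
                    z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                    if (
                        _in(shape, z2, y2, x2)
                        and valid[z2, y2, x2]
                        and bins[z2, y2, x2] == bins[z, y, x]
                    ):
                        dep += 1
                deps[(int(bins[z, y, x]), dep)] += 1
                n += 1
    col: dict[int, int] = defaultdict(int)
    for (g, d), c in deps.items():
        col[d] += c
    return {
        "SmallNumberEmphasis": sum(c / (d + 1) ** 2 for (g, d), c in deps.items()) / n,
        "LargeNumberEmphasis": sum(c * (d + 1) ** 2 for (g, d), c in deps.items()) / n,
        "NumberNonuniformity": sum(c**2 for c in col.values()) / n,
        "SecondMoment": sum(c**2 for c in deps.values()) / n,
        "EntropyNGL": -sum(
            (c / n) * math.log(c / n) for c in deps.values()
        ),
    }


def ngtdm_oracle(bins: np.ndarray, valid: np.ndarray, eps: float = 1e-6) -> dict[str, float]:
    """Coarseness / contrast / busyness by direct neighborhood means."""
    shape = bins.shape
    s: dict[int, float] = defaultdict(float)
    cnt: dict[int, int] = defaultdict(int)
    n = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not valid[z, y, x]:
                    continue
                nbs = [
                    float(bins[z + o[0], y + o[1], x + o[2]])
                    for o in NB26
                    if _in(shape, z + o[0], y + o[1], x + o[2])
                    and valid[z + o[0], y + o[1], x + o[2]]
                ]
                if not nbs:
                    continue
                g = int(bins[z, y, x])
                s[g] += abs(g - sum(nbs) / len(nbs))
                cnt[g] += 1
                n += 1
    if n == 0:
        return {"Coarseness": 1.0 / eps, "ContrastNGL": 0.0, "Busyness": 0.0}
    p = {g: c / n for g, c in cnt.items()}
    ps = sum(p[g] * s[g] for g in p)
    coarseness = 1.0 / max(ps, eps)
    ngp = len(p)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in p for j in p)
            / (ngp * (ngp - 1))
            * (sum(s.values()) / n)
        )
    else:
        contrast = 0.0
    den = sum(abs(i * p[i] - j * p[j]) for i in p for j in p)
    busyness = ps / den if den > 0 else 0.0
    return {"Coarseness": coarseness, "ContrastNGL": contrast, "Busyness": busyness}


def auc_pair_oracle(scores, labels, positive="malignant") -> float:
    """AUC as the mean over positive-negative pairs of [s_p > s_n] + 0.5[tie]."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_patch(rng: np.random.Generator, n_bins: int, p_invalid: float = 0.0):
    """A random 5x5x5 patch; optionally with an invalid corner region."""
    bins = rng.integers(1, n_bins + 1, size=(5, 5, 5))
    valid = np.ones((5, 5, 5), dtype=bool)
    if p_invalid > 0 and rng.random() < p_invalid:
        # carve an out-of-image corner, as happens at volume boundaries
        nz, ny, nx = rng.integers(1, 3, size=3)
        valid[:nz, :ny, :nx] = False
    return bins, valid
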