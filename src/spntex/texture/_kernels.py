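"""Numba kernels for per-patch texture-matrix features.

One call computes, for a single gray-level patch (typically 5x5x5 voxels
with validity flags for out-of-image positions), the 41 matrix-based
features: 22 co-occurrence (GLCM), 11 run-length (GLRLM), 5 neighboring
gray-level dependence (NGLDM) and 3 neighborhood gray-tone difference
(NGTDM) features.

Directional scheme: GLCM and GLRLM use 4 in-plane directions (0, 45, 90,
135 degrees at distance 1) in each of the three orthogonal planes — 12
plane-direction combinations in total (the three axis directions each occur
in two planes and therefore carry double weight).  Features, not matrices,
are averaged over the combinations.  NGLDM and NGTDM use the full
26-connected distance-1 neighborhood.

Gray levels enter every formula through their actual bin values (1..n_bins),
not through compact indices, so features are invariant to relabeling only
in the ways the definitions themselves are.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 4 in-plane directions x 3 orthogonal planes, axis order (slice, row, col).
OFFSETS = np.array(
    [
        # plane spanned by axes (1, 2) -- axial
        (0, 0, 1), (0, 1, 1), (0, 1, 0), (0, 1, -1),
        # plane spanned by axes (0, 2) -- coronal
        (0, 0, 1), (1, 0, 1), (1, 0, 0), (1, 0, -1),
        # plane spanned by axes (0, 1) -- sagittal
        (0, 1, 0), (1, 1, 0), (1, 0, 0), (1, -1, 0),
    ],
    dtype=np.int64,
)

# 26-connected neighborhood offsets.
_nb = []
for _dz in (-1, 0, 1):
    for _dy in (-1, 0, 1):
        for _dx in (-1, 0, 1):
            if _dz or _dy or _dx:
                _nb.append((_dz, _dy, _dx))
NEIGHBORS26 = np.array(_nb, dtype=np.int64)

N_GLCM, N_GLRLM, N_NGLDM, N_NGTDM = 22, 11, 5, 3
N_MATRIX = N_GLCM + N_GLRLM + N_NGLDM + N_NGTDM

COARSENESS_EPS = 1e-6


@njit(cache=True)
def _compact_levels(bins, valid):
    """Sorted unique bin values among valid voxels, plus a compact-index grid."""
    p0, p1, p2 = bins.shape
    vals = np.empty(p0 * p1 * p2, dtype=np.int64)
    n = 0
    for z in range(p0):
        for y in range(p1):
            for x in range(p2):
                if valid[z, y, x]:
                    vals[n] = bins[z, y, x]
                    n += 1
    vals = np.sort(vals[:n])
    levels = np.empty(n, dtype=np.int64)
    g = 0
    for k in range(n):
        if k == 0 or vals[k] != vals[k - 1]:
            levels[g] = vals[k]
            g += 1
    levels = levels[:g]
    idx = np.full((p0, p1, p2), -1, dtype=np.int64)
    for z in range(p0):
        for y in range(p1):
            for x in range(p2):
                if valid[z, y, x]:
                    idx[z, y, x] = np.searchsorted(levels, bins[z, y, x])
    return levels, idx, n


@njit(cache=True)
def _glcm_direction(C, total, lv, n_bins, out):
    """22 co-occurrence features from one direction's symmetric count matrix."""
    G = C.shape[0]
    px = np.zeros(G)
    for i in range(G):
        s = 0.0
        for j in range(G):
            s += C[i, j]
        px[i] = s / total

    mu = 0.0
    for i in range(G):
        mu += lv[i] * px[i]
    var = 0.0
    for i in range(G):
        var += (lv[i] - mu) ** 2 * px[i]

    psum = np.zeros(2 * n_bins + 1)
    pdiff = np.zeros(n_bins + 1)

    asm = 0.0
    contrast = 0.0
    corr_num = 0.0
    ssvar = 0.0
    idm = 0.0
    entropy = 0.0
    maxprob = 0.0
    diagmom = 0.0
    dissim = 0.0
    invdiff = 0.0
    shade = 0.0
    prom = 0.0
    hxy1 = 0.0

    for i in range(G):
        for j in range(G):
            c = C[i, j]
            if c == 0.0:
                continue
            p = c / total
            vi = lv[i]
            vj = lv[j]
            d = abs(vi - vj)
            s = vi + vj
            asm += p * p
            contrast += p * d * d
            corr_num += p * vi * vj
            ssvar += p * (vi - mu) ** 2
            idm += p / (1.0 + d * d)
            entropy -= p * np.log(p)
            if p > maxprob:
                maxprob = p
            diagmom += p * d * 0.5 * s
            dissim += p * d
            invdiff += p / (1.0 + d)
            shade += p * (s - 2.0 * mu) ** 3
            prom += p * (s - 2.0 * mu) ** 4
            hxy1 -= p * (np.log(px[i]) + np.log(px[j]))
            si = int(s)
            di = int(d)
            psum[si] += p
            pdiff[di] += p

    correlation = (corr_num - mu * mu) / var if var > 0.0 else 0.0

    sumavg = 0.0
    sument = 0.0
    sumenergy = 0.0
    for k in range(2 * n_bins + 1):
        q = psum[k]
        if q > 0.0:
            sumavg += k * q
            sument -= q * np.log(q)
            sumenergy += q * q
    sumvar = 0.0
    for k in range(2 * n_bins + 1):
        q = psum[k]
        if q > 0.0:
            sumvar += (k - sumavg) ** 2 * q

    diffavg = 0.0
    diffent = 0.0
    diffenergy = 0.0
    for k in range(n_bins + 1):
        q = pdiff[k]
        if q > 0.0:
            diffavg += k * q
            diffent -= q * np.log(q)
            diffenergy += q * q
    diffvar = 0.0
    for k in range(n_bins + 1):
        q = pdiff[k]
        if q > 0.0:
            diffvar += (k - diffavg) ** 2 * q

    hx = 0.0
    for i in range(G):
        if px[i] > 0.0:
            hx -= px[i] * np.log(px[i])
    hxy2 = 2.0 * hx  # closed form for the symmetric product distribution

    imc1 = (entropy - hxy1) / hx if hx > 0.0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = np.sqrt(arg) if arg > 0.0 else 0.0

    # Maximal correlation coefficient: second-largest |eigenvalue| of the
    # symmetrized transition matrix A = D^-1/2 P D^-1/2 (restricted to
    # levels participating in this direction), which shares its squared
    # spectrum with the classic Q matrix.
    keep = np.empty(G, dtype=np.int64)
    g2 = 0
    for i in range(G):
        if px[i] > 0.0:
            keep[g2] = i
            g2 += 1
    if g2 < 2:
        mcc = 0.0
    else:
        A = np.empty((g2, g2))
        for a in range(g2):
            ia = keep[a]
            for b in range(g2):
                ib = keep[b]
                A[a, b] = (C[ia, ib] / total) / np.sqrt(px[ia] * px[ib])
        w = np.linalg.eigvalsh(A)
        mcc = max(abs(w[0]), abs(w[g2 - 2]))
        if mcc > 1.0:
            mcc = 1.0

    out[0] += asm
    out[1] += contrast
    out[2] += correlation
    out[3] += ssvar
    out[4] += idm
    out[5] += sumavg
    out[6] += sumvar
    out[7] += sument
    out[8] += entropy
    out[9] += diffvar
    out[10] += diffent
    out[11] += imc1
    out[12] += imc2
    out[13] += mcc
    out[14] += maxprob
    out[15] += diagmom
    out[16] += dissim
    out[17] += diffenergy
    out[18] += invdiff
    out[19] += sumenergy
    out[20] += shade
    out[21] += prom


@njit(cache=True)
def _glrlm_direction(bins, valid, idx, lv, d0, d1, d2, n_valid, out):
    """11 run-length features for one direction (runs break on invalid cells)."""
    p0, p1, p2 = bins.shape
    G = lv.shape[0]
    maxlen = max(p0, max(p1, p2))
    rg = np.zeros(G)
    rl = np.zeros(maxlen)
    nr = 0.0
    sre = 0.0
    lre = 0.0
    lgle = 0.0
    hgle = 0.0
    srlgle = 0.0
    srhgle = 0.0
    lrlgle = 0.0
    lrhgle = 0.0

    for z in range(p0):
        for y in range(p1):
            for x in range(p2):
                # only start walking at line starts
                pz, py, px_ = z - d0, y - d1, x - d2
                if 0 <= pz < p0 and 0 <= py < p1 and 0 <= px_ < p2:
                    continue
                cz, cy, cx = z, y, x
                run_g = -1
                run_l = 0
                while 0 <= cz < p0 and 0 <= cy < p1 and 0 <= cx < p2:
                    if not valid[cz, cy, cx]:
                        if run_l > 0:
                            v = lv[run_g]
                            l2 = float(run_l * run_l)
                            v2 = v * v
                            nr += 1.0
                            rg[run_g] += 1.0
                            rl[run_l - 1] += 1.0
                            sre += 1.0 / l2
                            lre += l2
                            lgle += 1.0 / v2
                            hgle += v2
                            srlgle += 1.0 / (v2 * l2)
                            srhgle += v2 / l2
                            lrlgle += l2 / v2
                            lrhgle += v2 * l2
                            run_l = 0
                            run_g = -1
                    else:
                        g = idx[cz, cy, cx]
                        if run_l > 0 and g == run_g:
                            run_l += 1
                        else:
                            if run_l > 0:
                                v = lv[run_g]
                                l2 = float(run_l * run_l)
                                v2 = v * v
                                nr += 1.0
                                rg[run_g] += 1.0
                                rl[run_l - 1] += 1.0
                                sre += 1.0 / l2
                                lre += l2
                                lgle += 1.0 / v2
                                hgle += v2
                                srlgle += 1.0 / (v2 * l2)
                                srhgle += v2 / l2
                                lrlgle += l2 / v2
                                lrhgle += v2 * l2
                            run_g = g
                            run_l = 1
                    cz += d0
                    cy += d1
                    cx += d2
                if run_l > 0:
                    v = lv[run_g]
                    l2 = float(run_l * run_l)
                    v2 = v * v
                    nr += 1.0
                    rg[run_g] += 1.0
                    rl[run_l - 1] += 1.0
                    sre += 1.0 / l2
                    lre += l2
                    lgle += 1.0 / v2
                    hgle += v2
                    srlgle += 1.0 / (v2 * l2)
                    srhgle += v2 / l2
                    lrlgle += l2 / v2
                    lrhgle += v2 * l2

    if nr == 0.0:
        return
    gln = 0.0
    for g in range(G):
        gln += rg[g] * rg[g]
    rln = 0.0
    for k in range(maxlen):
        rln += rl[k] * rl[k]

    out[0] += sre / nr
    out[1] += lre / nr
    out[2] += gln / nr
    out[3] += rln / nr
    out[4] += nr / n_valid
    out[5] += lgle / nr
    out[6] += hgle / nr
    out[7] += srlgle / nr
    out[8] += srhgle / nr
    out[9] += lrlgle / nr
    out[10] += lrhgle / nr


@njit(cache=True)
def matrix_features_patch(bins, valid, n_bins, offsets, neighbors):
    """All 41 matrix features of one patch; see module docstring for layout.

    Returns a float64 vector: [22 GLCM | 11 GLRLM | 5 NGLDM | 3 NGTDM].
    """
    p0, p1, p2 = bins.shape
    out = np.zeros(N_MATRIX)
    levels, idx, n_valid = _compact_levels(bins, valid)
    G = levels.shape[0]
    if n_valid == 0:
        return out
    lv = levels.astype(np.float64)

    # --- GLCM over the 12 plane-direction combinations ------------------
    glcm = out[:N_GLCM]
    ndir_used = 0
    for k in range(offsets.shape[0]):
        d0, d1, d2 = offsets[k, 0], offsets[k, 1], offsets[k, 2]
        C = np.zeros((G, G))
        npairs = 0
        for z in range(p0):
            for y in range(p1):
                for x in range(p2):
                    if not valid[z, y, x]:
                        continue
                    z2, y2, x2 = z + d0, y + d1, x + d2
                    if 0 <= z2 < p0 and 0 <= y2 < p1 and 0 <= x2 < p2 and valid[z2, y2, x2]:
                        a = idx[z, y, x]
                        b = idx[z2, y2, x2]
                        C[a, b] += 1.0
                        C[b, a] += 1.0
                        npairs += 1
        if npairs == 0:
            continue
        _glcm_direction(C, 2.0 * npairs, lv, n_bins, glcm)
        ndir_used += 1
    if ndir_used > 0:
        for f in range(N_GLCM):
            out[f] /= ndir_used

    # --- GLRLM over the same 12 combinations -----------------------------
    glrlm = out[N_GLCM:N_GLCM + N_GLRLM]
    for k in range(offsets.shape[0]):
        _glrlm_direction(
            bins, valid, idx, lv,
            offsets[k, 0], offsets[k, 1], offsets[k, 2],
            float(n_valid), glrlm,
        )
    for f in range(N_GLCM, N_GLCM + N_GLRLM):
        out[f] /= offsets.shape[0]

    # --- NGLDM + NGTDM with the 26-connected neighborhood ----------------
    Q = np.zeros((G, 27))
    s_g = np.zeros(G)
    n_g = np.zeros(G)
    n_ngtdm = 0.0
    for z in range(p0):
        for y in range(p1):
            for x in range(p2):
                if not valid[z, y, x]:
                    continue
                g = idx[z, y, x]
                dep = 0
                nnb = 0
                nbsum = 0.0
                for k in range(neighbors.shape[0]):
                    z2 = z + neighbors[k, 0]
                    y2 = y + neighbors[k, 1]
                    x2 = x + neighbors[k, 2]
                    if 0 <= z2 < p0 and 0 <= y2 < p1 and 0 <= x2 < p2 and valid[z2, y2, x2]:
                        nnb += 1
                        nbsum += bins[z2, y2, x2]
                        if bins[z2, y2, x2] == bins[z, y, x]:
                            dep += 1
                Q[g, dep] += 1.0
                if nnb > 0:
                    s_g[g] += abs(bins[z, y, x] - nbsum / nnb)
                    n_g[g] += 1.0
                    n_ngtdm += 1.0

    base = N_GLCM + N_GLRLM
    ntot = float(n_valid)
    sne = 0.0
    lne = 0.0
    nnu = 0.0
    sm = 0.0
    ent = 0.0
    for dep in range(27):
        col = 0.0
        for g in range(G):
            q = Q[g, dep]
            if q > 0.0:
                w = float((dep + 1) * (dep + 1))
                sne += q / w
                lne += q * w
                sm += q * q
                p = q / ntot
                ent -= p * np.log(p)
            col += q
        nnu += col * col
    out[base + 0] = sne / ntot
    out[base + 1] = lne / ntot
    out[base + 2] = nnu / ntot
    out[base + 3] = sm / ntot
    out[base + 4] = ent

    base = N_GLCM + N_GLRLM + N_NGLDM
    if n_ngtdm > 0.0:
        ps_sum = 0.0
        s_sum = 0.0
        ngp = 0
        for g in range(G):
            if n_g[g] > 0.0:
                ngp += 1
                ps_sum += (n_g[g] / n_ngtdm) * s_g[g]
                s_sum += s_g[g]
        coarseness = 1.0 / max(ps_sum, COARSENESS_EPS)
        contrast_ngl = 0.0
        if ngp > 1:
            acc = 0.0
            for i in range(G):
                if n_g[i] == 0.0:
                    continue
                for j in range(G):
                    if n_g[j] == 0.0:
                        continue
                    acc += (n_g[i] / n_ngtdm) * (n_g[j] / n_ngtdm) * (lv[i] - lv[j]) ** 2
            contrast_ngl = acc / (ngp * (ngp - 1)) * (s_sum / n_ngtdm)
        busy_den = 0.0
        for i in range(G):
            if n_g[i] == 0.0:
                continue
            for j in range(G):
                if n_g[j] == 0.0:
                    continue
                busy_den += abs(lv[i] * n_g[i] / n_ngtdm - lv[j] * n_g[j] / n_ngtdm)
        busyness = ps_sum / busy_den if busy_den > 0.0 else 0.0
        out[base + 0] = coarseness
        out[base + 1] = contrast_ngl
        out[base + 2] = busyness
    else:
        out[base + 0] = 1.0 / COARSENESS_EPS
        out[base + 1] = 0.0
        out[base + 2] = 0.0

    return out
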