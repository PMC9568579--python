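"""Independent brute-force oracles for texture, agreement and dissimilarity.

Everything here is written as plain per-voxel / per-pair loops, deliberately
sharing no code with the package implementations it checks.
"""

import math
from itertools import product

import numpy as np


def glcm_oracle(levels, mask):
    """IMC1/IDMN by exhaustive enumeration of all distance-1 voxel pairs."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    ng = int(levels[mask].max())
    P = np.zeros((ng, ng))
    shape = levels.shape
    offsets = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in offsets:
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2] \
                    and mask[z2, y2, x2]:
                P[levels[z, y, x] - 1, levels[z2, y2, x2] - 1] += 1
    total = P.sum()
    if total == 0 or ng == 1:
        return {"imc1": 0.0, "idmn": 1.0}
    p = P / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    hxy = -sum(v * math.log2(v) for v in p.ravel() if v > 0)
    hxy1 = 0.0
    for i in range(ng):
        for j in range(ng):
            if p[i, j] > 0 and px[i] * py[j] > 0:
                hxy1 -= p[i, j] * math.log2(px[i] * py[j])
    denom = max(hx, hy)
    imc1 = 0.0 if denom <= 0 else (hxy - hxy1) / denom
    idmn = 0.0
    for i in range(ng):
        for j in range(ng):
            idmn += p[i, j] / (1.0 + (i - j) ** 2 / ng**2)
    return {"imc1": imc1, "idmn": idmn}


def gldm_oracle(levels, mask, alpha=0):
    """LDE / LDHGLE / dependence variance by per-voxel neighbor counting."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = levels.shape
    offsets = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    entries = []  # (gray level j, dependence size k) per voxel
    for z, y, x in np.argwhere(mask):
        dep = 1
        for dz, dy, dx in offsets:
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2] \
                    and mask[z2, y2, x2] \
                    and abs(int(levels[z, y, x]) - int(levels[z2, y2, x2])) <= alpha:
                dep += 1
        entries.append((int(levels[z, y, x]), dep))
    nz = len(entries)
    lde = sum(k * k for _, k in entries) / nz
    ldhgle = sum(j * j * k * k for j, k in entries) / nz
    mu_k = sum(k for _, k in entries) / nz
    dep_var = sum((k - mu_k) ** 2 for _, k in entries) / nz
    return {"lde": lde, "ldhgle": ldhgle, "dependence_variance": dep_var}


def ccc_oracle(x, y):
    """Lin's CCC from its closed form with explicit population moments."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


def cosine_dissimilarity_oracle(a, b):
    a = list(map(float, a))
    b = list(map(float, b))
    dot = sum(u * v for u, v in zip(a, b))
    na = math.sqrt(sum(u * u for u in a))
    nb = math.sqrt(sum(v * v for v in b))
    return 1.0 - dot / (na * nb)


def monte_carlo_ath_oracle(angular_spread, n_lesions, n_reps, rng):
    """Expected average pairwise dissimilarity of the angular construction,
    simulated directly from its definition (angles on a 2D plane)."""
    means = []
    for _ in range(n_reps):
        thetas = rng.uniform(0.0, angular_spread, size=n_lesions)
        total, count = 0.0, 0
        for i in range(n_lesions):
            for j in range(i + 1, n_lesions):
                total += 1.0 - math.cos(thetas[i] - thetas[j])
                count += 1
        means.append(total / count)
    return float(np.mean(means)), float(np.std(means, ddof=1))
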