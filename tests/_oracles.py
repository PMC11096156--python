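"""Independent brute-force oracles for the texture descriptors.

Every function here recomputes a descriptor with explicit double loops
and no library shortcuts, so that the vectorized implementations in
``pearloct.features`` can be checked against a second, independent
derivation on small patches.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(q: np.ndarray, distance: int, angle_deg: float, levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by pixel-pair enumeration.

    A pixel (r, c) pairs with (r + round(d sin a), c + round(d cos a));
    both orders are counted (symmetry).
    """
    a = math.radians(angle_deg)
    dr = int(round(distance * math.sin(a)))
    dc = int(round(distance * math.cos(a)))
    counts = np.zeros((levels, levels))
    n_rows, n_cols = q.shape
    for r in range(n_rows):
        for c in range(n_cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    total = counts.sum()
    return counts / total if total else counts


def glcm_statistics(p: np.ndarray) -> dict[str, float]:
    """Entropy (bits), energy (ASM), correlation, contrast by double loop."""
    levels = p.shape[0]
    entropy = energy = contrast = 0.0
    mu_i = mu_j = 0.0
    for i in range(levels):
        for j in range(levels):
            v = p[i, j]
            if v > 0:
                entropy -= v * math.log2(v)
            energy += v * v
            contrast += v * (i - j) ** 2
            mu_i += i * v
            mu_j += j * v
    var_i = var_j = cov = 0.0
    for i in range(levels):
        for j in range(levels):
            v = p[i, j]
            var_i += (i - mu_i) ** 2 * v
            var_j += (j - mu_j) ** 2 * v
            cov += (i - mu_i) * (j - mu_j) * v
    if var_i <= 1e-15 or var_j <= 1e-15:
        corr = 0.0
    else:
        corr = cov / math.sqrt(var_i * var_j)
    return {"entropy": entropy, "energy": energy, "correlation": corr, "contrast": contrast}


# ---------------------------------------------------------------------------
# LBP

def _bilinear_zero_pad(img: np.ndarray, r: float, c: float) -> float:
    """Bilinear sample with constant-0 outside, mirroring skimage's kernel."""
    n_rows, n_cols = img.shape

    def at(ri: int, ci: int) -> float:
        if 0 <= ri < n_rows and 0 <= ci < n_cols:
            return float(img[ri, ci])
        return 0.0

    minr, minc = int(math.floor(r)), int(math.floor(c))
    dr, dc = r - minr, c - minc
    top = (1 - dc) * at(minr, minc) + dc * at(minr, minc + 1)
    bottom = (1 - dc) * at(minr + 1, minc) + dc * at(minr + 1, minc + 1)
    return (1 - dr) * top + dr * bottom


def lbp_code_image(img: np.ndarray, P: int, R: float) -> np.ndarray:
    """Plain LBP codes: bit i set when the i-th sampled neighbor >= center.

    Neighbor i sits at (r - R sin(2 pi i / P), c + R cos(2 pi i / P)),
    sampled bilinearly with zero outside the image.
    """
    n_rows, n_cols = img.shape
    codes = np.zeros((n_rows, n_cols))
    offsets = [
        (-R * math.sin(2 * math.pi * i / P), R * math.cos(2 * math.pi * i / P))
        for i in range(P)
    ]
    for r in range(n_rows):
        for c in range(n_cols):
            center = float(img[r, c])
            code = 0
            for i, (orow, ocol) in enumerate(offsets):
                val = _bilinear_zero_pad(img, r + orow, c + ocol)
                if val - center >= 0:
                    code += 1 << i
            codes[r, c] = code
    return codes


# ---------------------------------------------------------------------------
# CSAC

def csac_neighborhood(window: np.ndarray, eps: float = 1e-12) -> dict[str, float]:
    """The six CSAC indicators of one 3x3 window, pair by pair."""
    assert window.shape == (3, 3)
    w = window.astype(float)
    pairs = [
        (w[0, 0], w[2, 2]),  # NW / SE
        (w[0, 1], w[2, 1]),  # N / S
        (w[0, 2], w[2, 0]),  # NE / SW
        (w[1, 0], w[1, 2]),  # W / E
    ]
    neighbors = [w[0, 0], w[0, 1], w[0, 2], w[1, 0], w[1, 2], w[2, 0], w[2, 1], w[2, 2]]
    mu = sum(neighbors) / 8.0
    scov = sum((x - mu) * (y - mu) for x, y in pairs) / 4.0
    var = sum((x - mu) ** 2 for x in neighbors) / 8.0
    sac = scov / var if var > 0 else 0.0
    pair_means = [(x + y) / 2.0 for x, y in pairs]
    wvar = sum((x - m) ** 2 for (x, _y), m in zip(pairs, pair_means)) / 4.0
    bvar = sum((m - mu) ** 2 for m in pair_means) / 4.0
    svr = bvar / (wvar + eps)
    return {"scov": scov, "var": var, "bvar": bvar, "wvar": wvar, "svr": svr, "sac": sac}


def csac_means_stds(img: np.ndarray) -> np.ndarray:
    """Mean then std of each indicator over all interior neighborhoods."""
    keys = ("scov", "var", "bvar", "wvar", "svr", "sac")
    vals: dict[str, list[float]] = {k: [] for k in keys}
    for r in range(1, img.shape[0] - 1):
        for c in range(1, img.shape[1] - 1):
            ind = csac_neighborhood(img[r - 1 : r + 2, c - 1 : c + 2])
            for k in keys:
                vals[k].append(ind[k])
    means = [float(np.mean(vals[k])) for k in keys]
    stds = [float(np.std(vals[k])) for k in keys]
    return np.array(means + stds)


# ---------------------------------------------------------------------------
# LAWS

def _reflect(idx: int, n: int) -> int:
    """scipy 'reflect' boundary: (d c b a | a b c d)."""
    while idx < 0 or idx >= n:
        if idx < 0:
            idx = -idx - 1
        else:
            idx = 2 * n - idx - 1
    return idx


def laws_response(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlation with reflect boundary, element by element."""
    kr, kc = kernel.shape
    hr, hc = kr // 2, kc // 2
    out = np.zeros_like(img, dtype=float)
    n_rows, n_cols = img.shape
    for r in range(n_rows):
        for c in range(n_cols):
            acc = 0.0
            for i in range(kr):
                for j in range(kc):
                    rr = _reflect(r + i - hr, n_rows)
                    cc = _reflect(c + j - hc, n_cols)
                    acc += kernel[i, j] * img[rr, cc]
            out[r, c] = acc
    return out


# ---------------------------------------------------------------------------
# HOG

def hog_histograms(img: np.ndarray, cell: int, bins: int) -> np.ndarray:
    """Per-cell unsigned orientation histograms, pixel by pixel.

    Central differences in the interior, one-sided at the borders
    (matching ``np.gradient``); each pixel votes its magnitude into one
    bin of width 180/bins degrees.
    """
    n_rows, n_cols = img.shape
    a = img.astype(float)
    n_r, n_c = n_rows // cell, n_cols // cell
    hists = np.zeros((n_r * n_c, bins))
    for r in range(n_rows):
        for c in range(n_cols):
            if 0 < r < n_rows - 1:
                gy = (a[r + 1, c] - a[r - 1, c]) / 2.0
            elif r == 0:
                gy = a[1, c] - a[0, c]
            else:
                gy = a[r, c] - a[r - 1, c]
            if 0 < c < n_cols - 1:
                gx = (a[r, c + 1] - a[r, c - 1]) / 2.0
            elif c == 0:
                gx = a[r, 1] - a[r, 0]
            else:
                gx = a[r, c] - a[r, c - 1]
            mag = math.hypot(gx, gy)
            ori = math.degrees(math.atan2(gy, gx)) % 180.0
            b = min(int(ori / (180.0 / bins)), bins - 1)
            hists[(r // cell) * n_c + c // cell, b] += mag
    return hists


# ---------------------------------------------------------------------------
# FD

def box_count_fd(img: np.ndarray, box_sizes=(2, 4, 8, 16, 32, 64), gray_range: int = 256) -> float:
    """Differential box counting by explicit block loops."""
    a = img.astype(float)
    side = min(a.shape)
    log_inv_s, log_n = [], []
    for s in box_sizes:
        if s > side:
            continue
        h = s * gray_range / side
        total = 0.0
        for r0 in range(0, a.shape[0] - s + 1, s):
            for c0 in range(0, a.shape[1] - s + 1, s):
                block = a[r0 : r0 + s, c0 : c0 + s]
                total += math.ceil(block.max() / h) - math.ceil(block.min() / h) + 1
        log_inv_s.append(math.log(1.0 / s))
        log_n.append(math.log(total))
    return float(np.polyfit(log_inv_s, log_n, 1)[0])
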