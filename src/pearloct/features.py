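"""The seven-family speckle texture descriptor bank (237 features).

Each 128x128 flattened subsurface patch is digitized into one ordered
237-element vector:

=========  ====================================================  ======
family     contents                                              length
=========  ====================================================  ======
FD         differential box-counting fractal dimension              1
GLCM       mean+std over 4 angles of {entropy, energy,
           correlation, contrast} at distances 1..10               80
LBP        mean+std of the LBP code image at 14 (P, R) pairs       28
Gabor      mean+std of response magnitude, 5 wavelengths x
           8 orientations                                          80
HOG        per-bin mean+std of 1024 4x4-cell 9-bin histograms      18
LAWS       mean |response| + std of response for 9 Laws
           kernel combinations                                     18
CSAC       mean+std of 6 center-symmetric auto-correlation
           indicators over all 3x3 neighborhoods                   12
=========  ====================================================  ======

Ordering is fixed (family order above; statistic-major / distance-minor
for GLCM, listed pair order for LBP, wavelength-major for Gabor) so
vectors are comparable across runs; :func:`feature_names` exposes the
layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import graycomatrix, local_binary_pattern
from skimage.filters import gabor_kernel

from .preprocess import RoiPatch

__all__ = [
    "FeatureVector",
    "GlcmConfig",
    "GaborConfig",
    "LbpConfig",
    "HogConfig",
    "LAWS_MASKS_1D",
    "LAWS_COMBOS",
    "CSAC_INDICATORS",
    "FAMILY_BLOCKS",
    "N_FEATURES",
    "feature_names",
    "extract_fd",
    "extract_glcm",
    "extract_lbp",
    "extract_gabor",
    "extract_hog",
    "extract_laws",
    "extract_csac",
    "assemble_features",
]

N_FEATURES = 237


class FeatureError(ValueError):
    """Invalid input to a texture descriptor."""


# ---------------------------------------------------------------------------
# configuration types

@dataclass(frozen=True)
class GlcmConfig:
    """4 statistics x 10 distances x 4 angles co-occurrence setup."""

    statistics: tuple[str, ...] = ("entropy", "energy", "correlation", "contrast")
    distances: tuple[int, ...] = tuple(range(1, 11))
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gray_levels: int = 16


@dataclass(frozen=True)
class GaborConfig:
    """5 carrier wavelengths x 8 orientations; sigma from a 1-octave bandwidth."""

    wavelengths: tuple[float, ...] = (2.0, 4.0, 8.0, 10.0, 12.0)
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    bandwidth: float = 1.0


@dataclass(frozen=True)
class LbpConfig:
    """The 14 neighbor/radius pairs of the LBP sweep."""

    neighbor_radius_pairs: tuple[tuple[int, int], ...] = (
        (4, 1), (4, 2),
        (8, 1), (8, 2), (8, 3),
        (12, 1), (12, 2), (12, 3), (12, 4),
        (16, 1), (16, 2), (16, 3), (16, 4), (16, 5),
    )


@dataclass(frozen=True)
class HogConfig:
    """4x4-pixel cells, 9 unsigned orientation bins, one block = whole ROI."""

    cell_size: int = 4
    bins: int = 9


# Laws 1-D masks: level, edge, spot, ripple (3- and 5-tap documented constants)
LAWS_MASKS_1D = {
    "L3": np.array([1.0, 2.0, 1.0]),
    "E3": np.array([-1.0, 0.0, 1.0]),
    "S3": np.array([-1.0, 2.0, -1.0]),
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

# the 9 selected combinations; L5L5 (pure level) is excluded, asymmetric
# pairs are averaged over both filter orders
LAWS_COMBOS = (
    ("L5", "E5"), ("L5", "S5"), ("L5", "R5"),
    ("E5", "S5"), ("E5", "R5"), ("E5", "E5"),
    ("S5", "R5"), ("S5", "S5"), ("R5", "R5"),
)

CSAC_INDICATORS = ("scov", "var", "bvar", "wvar", "svr", "sac")

_DEFAULT_GLCM = GlcmConfig()
_DEFAULT_GABOR = GaborConfig()
_DEFAULT_LBP = LbpConfig()
_DEFAULT_HOG = HogConfig()


def feature_names(
    glcm: GlcmConfig = _DEFAULT_GLCM,
    lbp: LbpConfig = _DEFAULT_LBP,
    gabor: GaborConfig = _DEFAULT_GABOR,
    hog: HogConfig = _DEFAULT_HOG,
) -> list[str]:
    """Ordered names of all 237 features."""
    names = ["fd"]
    for stat_kind in ("mean", "std"):
        for s in glcm.statistics:
            for d in glcm.distances:
                names.append(f"glcm_{stat_kind}_{s}_d{d}")
    for stat_kind in ("mean", "std"):
        for p, r in lbp.neighbor_radius_pairs:
            names.append(f"lbp_{stat_kind}_p{p}_r{r}")
    for stat_kind in ("mean", "std"):
        for w in gabor.wavelengths:
            for o in gabor.orientations_deg:
                names.append(f"gabor_{stat_kind}_w{w:g}_o{o:g}")
    for stat_kind in ("mean", "std"):
        for b in range(hog.bins):
            names.append(f"hog_bin{stat_kind}_{b}")
    for stat_kind in ("mean", "std"):
        for a, b in LAWS_COMBOS:
            names.append(f"laws_{stat_kind}_{a.lower()}{b.lower()}")
    for stat_kind in ("mean", "std"):
        for ind in CSAC_INDICATORS:
            names.append(f"csac_{stat_kind}_{ind}")
    assert len(names) == N_FEATURES
    return names


# (start, stop) slices of each family block within the 237-vector
FAMILY_BLOCKS = {
    "FD": (0, 1),
    "GLCM": (1, 81),
    "LBP": (81, 109),
    "Gabor": (109, 189),
    "HOG": (189, 207),
    "LAWS": (207, 225),
    "CSAC": (225, 237),
}


@dataclass
class FeatureVector:
    """The ordered 237-element texture feature vector of one ROI."""

    values: np.ndarray
    names: list[str] = field(default_factory=feature_names)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise FeatureError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(self.values)):
            bad = [self.names[i] for i in np.flatnonzero(~np.isfinite(self.values))]
            raise FeatureError(f"non-finite feature values: {bad[:5]}")

    def block(self, family: str) -> np.ndarray:
        a, b = FAMILY_BLOCKS[family]
        return self.values[a:b]


def _as_float(roi: RoiPatch | np.ndarray) -> np.ndarray:
    a = roi.pixels if isinstance(roi, RoiPatch) else np.asarray(roi)
    return a.astype(float)


# ---------------------------------------------------------------------------
# FD — differential box counting

def extract_fd(
    roi: RoiPatch | np.ndarray,
    box_sizes: Sequence[int] = (2, 4, 8, 16, 32, 64),
    gray_range: int = 256,
) -> float:
    """Fractal dimension by differential box counting.

    The gray surface over each ``s x s`` block is covered by boxes of
    height ``h = s * gray_range / side``; the block's box count is
    ``ceil(max/h) - ceil(min/h) + 1`` (a constant block needs one box).
    FD is the slope of ``log N(s)`` against ``log(1/s)``: 2 for a flat
    surface, approaching 3 for space-filling roughness.
    """
    a = _as_float(roi)
    if a.size == 0:
        raise FeatureError("empty ROI")
    side = min(a.shape)
    counts = []
    sizes = []
    for s in box_sizes:
        if s > side:
            continue
        h = s * gray_range / side
        nb_r, nb_c = a.shape[0] // s, a.shape[1] // s
        blocks = a[: nb_r * s, : nb_c * s].reshape(nb_r, s, nb_c, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        n = np.ceil(bmax / h) - np.ceil(bmin / h) + 1
        counts.append(n.sum())
        sizes.append(s)
    if len(sizes) < 2:
        raise FeatureError("ROI too small for box counting")
    slope = np.polyfit(np.log(1.0 / np.array(sizes)), np.log(counts), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# GLCM

def _glcm_statistic(p: np.ndarray, stat: str) -> float:
    """One Haralick-style statistic of a normalized co-occurrence matrix."""
    levels = p.shape[0]
    i, j = np.indices((levels, levels))
    if stat == "entropy":
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())
    if stat == "energy":
        return float((p**2).sum())
    if stat == "contrast":
        return float((p * (i - j) ** 2).sum())
    if stat == "correlation":
        mu_i = (i * p).sum()
        mu_j = (j * p).sum()
        var_i = ((i - mu_i) ** 2 * p).sum()
        var_j = ((j - mu_j) ** 2 * p).sum()
        if var_i <= 1e-15 or var_j <= 1e-15:
            return 0.0  # constant image: correlation undefined, reported as 0
        return float((((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j))
    raise FeatureError(f"unknown GLCM statistic {stat!r}")


def quantize(roi: RoiPatch | np.ndarray, levels: int, gray_range: int = 256) -> np.ndarray:
    """Uniformly quantize 8-bit gray levels into ``levels`` bins."""
    a = _as_float(roi)
    q = np.floor(a * levels / gray_range).astype(int)
    return np.clip(q, 0, levels - 1)


def extract_glcm(roi: RoiPatch | np.ndarray, cfg: GlcmConfig = _DEFAULT_GLCM) -> np.ndarray:
    """40 means followed by 40 stds of the per-angle GLCM statistics.

    For each (statistic, distance) combination the statistic is
    evaluated on the normalized symmetric co-occurrence matrix at each
    of the 4 angles; the 4 values are summarized by their mean and
    standard deviation.  Order is statistic-major, distance-minor.
    """
    a = _as_float(roi)
    if max(cfg.distances) >= min(a.shape):
        raise FeatureError("GLCM distance must be smaller than the ROI side")
    q = quantize(a, cfg.gray_levels).astype(np.uint8)
    angles = np.deg2rad(cfg.angles_deg)
    glcm = graycomatrix(
        q,
        distances=list(cfg.distances),
        angles=list(angles),
        levels=cfg.gray_levels,
        symmetric=True,
        normed=True,
    )
    means, stds = [], []
    for stat in cfg.statistics:
        for di in range(len(cfg.distances)):
            vals = np.array(
                [_glcm_statistic(glcm[:, :, di, ai], stat) for ai in range(len(angles))]
            )
            means.append(vals.mean())
            stds.append(vals.std())
    return np.array(means + stds)


# ---------------------------------------------------------------------------
# LBP

def extract_lbp(roi: RoiPatch | np.ndarray, cfg: LbpConfig = _DEFAULT_LBP) -> np.ndarray:
    """Mean and std of the plain LBP code image at the 14 (P, R) pairs.

    The whole ROI is one LBP cell.  Codes use the original convention
    (neighbor >= center sets the bit; bilinear interpolation off-grid);
    statistics are taken over pixels whose full neighborhood lies inside
    the ROI, so border padding never leaks into the summary.
    """
    a = roi.pixels if isinstance(roi, RoiPatch) else np.asarray(roi)
    if not np.issubdtype(a.dtype, np.integer):
        a = np.round(a).astype(np.int64)  # LBP compares gray levels exactly
    means, stds = [], []
    for p, r in cfg.neighbor_radius_pairs:
        codes = local_binary_pattern(a, P=p, R=r, method="default")
        m = int(np.ceil(r))
        interior = codes[m:-m, m:-m] if m > 0 else codes
        if interior.size == 0:
            raise FeatureError(f"ROI too small for LBP radius {r}")
        means.append(interior.mean())
        stds.append(interior.std())
    return np.array(means + stds)


# ---------------------------------------------------------------------------
# Gabor

def _gabor_bank(cfg: GaborConfig) -> list[np.ndarray]:
    """Complex kernels, wavelength-major, DC-corrected even part."""
    kernels = []
    for w in cfg.wavelengths:
        for o in cfg.orientations_deg:
            k = gabor_kernel(
                frequency=1.0 / w, theta=np.deg2rad(o), bandwidth=cfg.bandwidth
            )
            k = k - k.real.mean()  # zero-sum real part: no response to a constant
            kernels.append(k)
    return kernels


def _filter_magnitude(a: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size complex filtering with reflect padding (FFT convolution)."""
    pr = kernel.shape[0] // 2
    pc = kernel.shape[1] // 2
    padded = np.pad(a, ((pr, pr), (pc, pc)), mode="reflect")
    resp = fftconvolve(padded, kernel, mode="same")
    resp = resp[pr : pr + a.shape[0], pc : pc + a.shape[1]]
    return np.abs(resp)


def extract_gabor(roi: RoiPatch | np.ndarray, cfg: GaborConfig = _DEFAULT_GABOR) -> np.ndarray:
    """40 means followed by 40 stds of the Gabor response magnitudes.

    Each of the 5x8 (wavelength, orientation) filters is applied as a
    complex quadrature pair; the response-magnitude image is summarized
    by its mean and std.  Wavelength-major, orientation-minor order.
    """
    a = _as_float(roi)
    means, stds = [], []
    for k in _gabor_bank(cfg):
        mag = _filter_magnitude(a, k)
        means.append(mag.mean())
        stds.append(mag.std())
    return np.array(means + stds)


# ---------------------------------------------------------------------------
# HOG

def hog_cell_histograms(
    roi: RoiPatch | np.ndarray, cfg: HogConfig = _DEFAULT_HOG
) -> np.ndarray:
    """Per-cell unsigned orientation histograms, shape (n_cells, bins).

    Gradients by central differences; orientations folded to [0, 180);
    each pixel votes its full gradient magnitude into one 20-degree bin.
    No block normalization — the whole ROI is a single block.
    """
    a = _as_float(roi)
    if a.shape[0] % cfg.cell_size or a.shape[1] % cfg.cell_size:
        raise FeatureError("ROI side must be a multiple of the HOG cell size")
    gy, gx = np.gradient(a)
    mag = np.hypot(gx, gy)
    ori = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((ori / (180.0 / cfg.bins)).astype(int), cfg.bins - 1)
    cs = cfg.cell_size
    n_r, n_c = a.shape[0] // cs, a.shape[1] // cs
    hists = np.zeros((n_r * n_c, cfg.bins))
    cell_idx = (
        (np.arange(a.shape[0])[:, None] // cs) * n_c + np.arange(a.shape[1])[None, :] // cs
    )
    np.add.at(hists, (cell_idx.ravel(), bins.ravel()), mag.ravel())
    return hists


def extract_hog(roi: RoiPatch | np.ndarray, cfg: HogConfig = _DEFAULT_HOG) -> np.ndarray:
    """Per-bin mean then per-bin std of all 4x4-cell histograms (9 + 9)."""
    a = _as_float(roi)
    if a.shape != (128, 128):
        raise FeatureError("HOG expects a 128x128 ROI")
    hists = hog_cell_histograms(a, cfg)
    return np.concatenate([hists.mean(axis=0), hists.std(axis=0)])


# ---------------------------------------------------------------------------
# LAWS

def _laws_kernel(name_a: str, name_b: str) -> np.ndarray:
    return np.outer(LAWS_MASKS_1D[name_a], LAWS_MASKS_1D[name_b])


def _laws_response(a: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import correlate

    return correlate(a, kernel, mode="reflect")


def extract_laws(roi: RoiPatch | np.ndarray) -> np.ndarray:
    """Laws texture energy: 9 mean-|response| then 9 response stds.

    The ROI mean is subtracted first; asymmetric combinations (e.g.
    L5E5/E5L5) are averaged over both filter orders.
    """
    a = _as_float(roi)
    a = a - a.mean()
    means, stds = [], []
    for na, nb in LAWS_COMBOS:
        r1 = _laws_response(a, _laws_kernel(na, nb))
        if na == nb:
            means.append(np.abs(r1).mean())
            stds.append(r1.std())
        else:
            r2 = _laws_response(a, _laws_kernel(nb, na))
            means.append(0.5 * (np.abs(r1).mean() + np.abs(r2).mean()))
            stds.append(0.5 * (r1.std() + r2.std()))
    return np.array(means + stds)


# ---------------------------------------------------------------------------
# CSAC

def csac_maps(roi: RoiPatch | np.ndarray, eps: float = 1e-12) -> dict[str, np.ndarray]:
    """Per-neighborhood CSAC indicator maps over all interior pixels.

    For each 3x3 neighborhood with center-symmetric pairs
    (NW,SE), (N,S), (NE,SW), (W,E) and mu = mean of the 8 neighbors:

    * SCOV = 1/4 sum (x_i - mu)(x_i' - mu)  — gray texture covariance
    * VAR  = 1/8 sum_j (x_j - mu)^2         — local variance
    * SAC  = SCOV / VAR (0 when VAR = 0)    — normalized, shift/scale invariant
    * WVAR = 1/4 sum (x_i - m_i)^2, m_i = (x_i + x_i')/2 — within-pair
    * BVAR = 1/4 sum (m_i - mu)^2           — between-pair
    * SVR  = BVAR / (WVAR + eps)            — variance ratio
    """
    a = _as_float(roi)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise FeatureError("CSAC requires an ROI of at least 3x3 pixels")
    nw, n_, ne = a[:-2, :-2], a[:-2, 1:-1], a[:-2, 2:]
    w_, e_ = a[1:-1, :-2], a[1:-1, 2:]
    sw, s_, se = a[2:, :-2], a[2:, 1:-1], a[2:, 2:]
    pairs = [(nw, se), (n_, s_), (ne, sw), (w_, e_)]
    neighbors = [nw, n_, ne, w_, e_, sw, s_, se]
    mu = sum(neighbors) / 8.0
    scov = sum((x - mu) * (y - mu) for x, y in pairs) / 4.0
    var = sum((x - mu) ** 2 for x in neighbors) / 8.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sac = np.where(var > 0, scov / np.where(var > 0, var, 1.0), 0.0)
    pair_means = [(x + y) / 2.0 for x, y in pairs]
    # (x - m)^2 == (y - m)^2 within a center-symmetric pair: one term per pair
    wvar = sum((x - m) ** 2 for (x, _y), m in zip(pairs, pair_means)) / 4.0
    bvar = sum((m - mu) ** 2 for m in pair_means) / 4.0
    svr = bvar / (wvar + eps)
    return {"scov": scov, "var": var, "bvar": bvar, "wvar": wvar, "svr": svr, "sac": sac}


def extract_csac(roi: RoiPatch | np.ndarray) -> np.ndarray:
    """Mean of each CSAC indicator over all neighborhoods, then each std."""
    maps = csac_maps(roi)
    means = [maps[k].mean() for k in CSAC_INDICATORS]
    stds = [maps[k].std() for k in CSAC_INDICATORS]
    return np.array(means + stds)


# ---------------------------------------------------------------------------
# assembly

def assemble_features(
    roi: RoiPatch | np.ndarray,
    glcm: GlcmConfig = _DEFAULT_GLCM,
    lbp: LbpConfig = _DEFAULT_LBP,
    gabor: GaborConfig = _DEFAULT_GABOR,
    hog: HogConfig = _DEFAULT_HOG,
) -> FeatureVector:
    """Compute all seven families and concatenate in the fixed layout."""
    parts = []
    for family, fn in (
        ("FD", lambda: np.array([extract_fd(roi)])),
        ("GLCM", lambda: extract_glcm(roi, glcm)),
        ("LBP", lambda: extract_lbp(roi, lbp)),
        ("Gabor", lambda: extract_gabor(roi, gabor)),
        ("HOG", lambda: extract_hog(roi, hog)),
        ("LAWS", lambda: extract_laws(roi)),
        ("CSAC", lambda: extract_csac(roi)),
    ):
        try:
            parts.append(np.asarray(fn(), dtype=float))
        except Exception as exc:
            raise FeatureError(f"{family} extraction failed: {exc}") from exc
    values = np.concatenate(parts)
    return FeatureVector(values=values, names=feature_names(glcm, lbp, gabor, hog))
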