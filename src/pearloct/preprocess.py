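"""Automated nacre-surface location: denoise, edge fit, flatten, crop.

A pearl B-scan shows the nacre as a bright curved band whose apex
position and curvature vary from sample to sample.  The texture stage
needs a geometry-free 128x128 patch of subsurface speckle, so this
module (1) estimates the background noise level from the top 30 rows
and hard-thresholds at mu + 2*sigma, (2) finds the rough air/nacre edge
with the Canny detector, (3) fits a polynomial (degree 2 by default: a
spherical cap is locally quadratic) to the per-column edge, (4) shifts
every column by an integer offset so the fitted edge becomes a
horizontal line — integer shifts preserve the raw speckle pattern — and
(5) crops the 128x128 region of interest just below the flattened
surface, centered laterally.

All operations accept plain 2-D grayscale arrays (rows = depth, row 0
shallowest); the :class:`BScan` wrapper adds provenance for pipeline
I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import feature, filters

__all__ = [
    "BScan",
    "BackgroundStats",
    "SurfaceFit",
    "RoiPatch",
    "PreprocessError",
    "SurfaceNotFoundError",
    "background_stats",
    "denoise",
    "detect_rough_edge",
    "fit_surface",
    "flatten",
    "crop_roi",
    "locate_roi",
    "load_bscan",
]

N_BACKGROUND_ROWS = 30
ROI_SIZE = 128


class PreprocessError(ValueError):
    """Invalid input to a preprocessing operation."""


class SurfaceNotFoundError(PreprocessError):
    """The nacre surface could not be located in the image."""


@dataclass
class BScan:
    """A raw grayscale B-scan (rows = depth, row 0 shallowest)."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise PreprocessError("a B-scan must be a 2-D grayscale array")


@dataclass(frozen=True)
class BackgroundStats:
    """Noise statistics of the top background rows.

    ``threshold = mu + 2 * sigma`` is the hard denoising threshold; mu
    and sigma are the mean and standard deviation of the gray levels in
    the top 30 rows.
    """

    mu: float
    sigma: float

    @property
    def threshold(self) -> float:
        return self.mu + 2.0 * self.sigma


@dataclass
class SurfaceFit:
    """Per-column surface estimate: rough Canny edge and polynomial fit.

    ``rough_edge`` holds the topmost Canny row per column (NaN where no
    edge pixel was found).  After :func:`fit_surface`, ``poly_coeffs``
    (highest degree first, row as a function of column), ``fitted_edge``
    and ``residual_rms`` are populated.
    """

    rough_edge: np.ndarray
    poly_coeffs: np.ndarray | None = None
    fitted_edge: np.ndarray | None = None
    residual_rms: float | None = None


@dataclass
class RoiPatch:
    """A 128x128 flattened subsurface patch — the texture-analysis unit."""

    pixels: np.ndarray
    origin_row: int
    origin_col: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (ROI_SIZE, ROI_SIZE):
            raise PreprocessError(
                f"ROI must be {ROI_SIZE}x{ROI_SIZE}, got {self.pixels.shape}"
            )


def _pixels(img: BScan | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, BScan) else np.asarray(img)


def background_stats(img: BScan | np.ndarray) -> BackgroundStats:
    """Mean/std of the top 30 rows; threshold = mu + 2*sigma."""
    a = _pixels(img).astype(float)
    if a.shape[0] < N_BACKGROUND_ROWS:
        raise PreprocessError(
            f"image must have at least {N_BACKGROUND_ROWS} rows for background estimation"
        )
    top = a[:N_BACKGROUND_ROWS]
    return BackgroundStats(mu=float(top.mean()), sigma=float(top.std()))


def denoise(img: BScan | np.ndarray, stats: BackgroundStats) -> np.ndarray:
    """Hard-threshold: pixels <= threshold are zeroed, others kept."""
    a = _pixels(img)
    out = a.copy()
    out[a <= stats.threshold] = 0
    return out


def detect_rough_edge(img: BScan | np.ndarray, sigma: float = 2.0) -> SurfaceFit:
    """Topmost Canny edge row per column of a denoised B-scan.

    Hysteresis thresholds are derived from an Otsu split of the
    Gaussian-smoothed gradient magnitude (low = 0.5x, high = 1.0x), so
    the detector adapts to the band's contrast.  Columns without any
    edge pixel are NaN; if more than half the columns are missing, the
    surface is declared not found.
    """
    a = _pixels(img).astype(float)
    smoothed = filters.gaussian(a, sigma=sigma)
    gmag = filters.sobel(smoothed)
    if gmag.max() <= 0:
        raise SurfaceNotFoundError("surface not found: image has no gradient")
    t_high = filters.threshold_otsu(gmag)
    edges = feature.canny(
        a, sigma=sigma, low_threshold=0.5 * t_high, high_threshold=t_high
    )
    n_rows, n_cols = edges.shape
    rough = np.full(n_cols, np.nan)
    any_edge = edges.any(axis=0)
    first = edges.argmax(axis=0)
    rough[any_edge] = first[any_edge]
    if np.isnan(rough).sum() > 0.5 * n_cols:
        raise SurfaceNotFoundError(
            "surface not found: edge missing in more than half of the columns"
        )
    return SurfaceFit(rough_edge=rough)


def fit_surface(rough: SurfaceFit, degree: int = 2) -> SurfaceFit:
    """Least-squares polynomial fit of the rough edge over valid columns.

    Missing columns are excluded from the fit and filled by evaluating
    the fitted polynomial.
    """
    edge = rough.rough_edge
    valid = ~np.isnan(edge)
    if valid.sum() < degree + 1:
        raise PreprocessError(
            f"need at least {degree + 1} edge columns for a degree-{degree} fit"
        )
    cols = np.arange(edge.size, dtype=float)
    coeffs = np.polyfit(cols[valid], edge[valid], degree)
    fitted = np.polyval(coeffs, cols)
    resid = edge[valid] - fitted[valid]
    return SurfaceFit(
        rough_edge=edge,
        poly_coeffs=coeffs,
        fitted_edge=fitted,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def flatten(
    img: BScan | np.ndarray, fit: SurfaceFit, target_row: int = 20
) -> np.ndarray:
    """Zero everything above the fitted edge, then shift each column by an
    integer offset so the fitted edge lies on ``target_row``.

    Vacated pixels are zero-filled.  Raises if any column's shift would
    push the whole column content out of the frame.
    """
    if fit.fitted_edge is None:
        raise PreprocessError("fit_surface must be called before flatten")
    a = _pixels(img).copy()
    n_rows, n_cols = a.shape
    if fit.fitted_edge.size != n_cols:
        raise PreprocessError("surface fit width does not match the image")
    rr = np.arange(n_rows)[:, None]
    a[rr < fit.fitted_edge[None, :]] = 0
    shifts = np.round(target_row - fit.fitted_edge).astype(int)
    if np.any(np.abs(shifts) >= n_rows):
        raise PreprocessError("flattening shift pushes the nacre band out of frame")
    out = np.zeros_like(a)
    for c in range(n_cols):
        s = shifts[c]
        if s >= 0:
            out[s:, c] = a[: n_rows - s, c]
        else:
            out[: n_rows + s, c] = a[-s:, c]
    return out


def crop_roi(
    flat: BScan | np.ndarray,
    target_row: int = 20,
    offset: int = 2,
    source_id: str = "",
) -> RoiPatch:
    """Crop the 128x128 ROI just below the flattened surface line.

    Rows ``[target_row + offset, target_row + offset + 127]``, columns
    centered laterally.  The 2-row default offset keeps the bright
    surface specular line itself out of the texture patch.
    """
    a = _pixels(flat)
    n_rows, n_cols = a.shape
    r0 = target_row + offset
    c0 = n_cols // 2 - ROI_SIZE // 2
    if r0 < 0 or r0 + ROI_SIZE > n_rows or c0 < 0 or c0 + ROI_SIZE > n_cols:
        raise PreprocessError(
            f"ROI rows [{r0}, {r0 + ROI_SIZE}) / cols [{c0}, {c0 + ROI_SIZE}) "
            f"exceed image of shape {a.shape}"
        )
    return RoiPatch(
        pixels=a[r0 : r0 + ROI_SIZE, c0 : c0 + ROI_SIZE].copy(),
        origin_row=r0,
        origin_col=c0,
        source_id=source_id,
    )


def locate_roi(
    img: BScan | np.ndarray,
    degree: int = 2,
    target_row: int = 20,
    roi_offset: int = 2,
    canny_sigma: float = 2.0,
    max_residual_rms: float = 20.0,
) -> tuple[RoiPatch, BackgroundStats, SurfaceFit]:
    """Full target-location chain: denoise -> edge -> fit -> flatten -> crop.

    A polynomial fit with residual RMS above ``max_residual_rms`` pixels
    means the detected "edge" is scattered noise, not a nacre surface.
    """
    stats = background_stats(img)
    clean = denoise(img, stats)
    rough = detect_rough_edge(clean, sigma=canny_sigma)
    fit = fit_surface(rough, degree=degree)
    if fit.residual_rms > max_residual_rms:
        raise SurfaceNotFoundError(
            f"surface not found: edge fit residual {fit.residual_rms:.1f} px "
            f"exceeds {max_residual_rms} px"
        )
    # a real nacre surface is bright just below the fitted edge; scattered
    # noise edges leave mostly-zero pixels there
    a = clean.astype(float)
    rows = np.clip(np.round(fit.fitted_edge).astype(int), 0, a.shape[0] - 6)
    below = np.stack([a[rows + k, np.arange(a.shape[1])] for k in range(1, 6)])
    if np.median(below) <= stats.threshold:
        raise SurfaceNotFoundError(
            "surface not found: no bright band below the fitted edge"
        )
    flat = flatten(clean, fit, target_row=target_row)
    source = img.source_id if isinstance(img, BScan) else ""
    roi = crop_roi(flat, target_row=target_row, offset=roi_offset, source_id=source)
    return roi, stats, fit


def load_bscan(path: str | Path) -> BScan:
    """Read an 8-bit grayscale PNG/TIFF B-scan."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
    return BScan(pixels=arr, source_id=path.name)
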