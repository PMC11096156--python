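"""Synthetic pearl OCT B-scan generator.

Real pearl B-scans show a bright, gently curved nacre band over a dark
noisy background; the band interior carries a multiplicative speckle
texture whose second-order statistics (contrast, correlation lengths)
track the nacre microstructure and hence the luster grade.  This module
emulates exactly those features so that every downstream stage — surface
segmentation, flattening, the texture descriptor bank and the grading
models — can be exercised and validated without proprietary pearl images.

The speckle field is a correlated log-normal multiplicative field: white
Gaussian noise is low-pass filtered with per-axis Gaussian kernels (the
correlation lengths), rescaled in the log domain and exponentiated.  This
gives an exactly unit-mean, nonnegative field whose std/mean equals the
requested ``speckle_contrast`` and whose autocorrelation widths are set
by the filter sigmas — the two knobs the texture bank is meant to detect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SpeckleParams",
    "SynthConfig",
    "LabeledDataset",
    "GRADES",
    "default_class_params",
    "generate_bscan",
    "generate_dataset",
    "surface_rows",
    "band_mask",
    "save_dataset",
]

GRADES = ("A", "B", "C", "D")


class SimulationError(ValueError):
    """Raised for invalid generator configurations or labels."""


@dataclass(frozen=True)
class SpeckleParams:
    """Per-grade speckle texture parameters.

    mean_intensity
        Band brightness at the surface, gray levels in [0, 255].
    speckle_contrast
        std/mean of the multiplicative field (dimensionless, >= 0).
    correlation_length_axial, correlation_length_lateral
        Gaussian autocorrelation sigmas of the field, pixels (>= 1
        lateral; the axial value may be sub-pixel for nearly white
        axial texture).
    depth_decay
        Exponential attenuation per pixel of depth below the surface.
    """

    mean_intensity: float = 120.0
    speckle_contrast: float = 0.3
    correlation_length_axial: float = 1.5
    correlation_length_lateral: float = 2.5
    depth_decay: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_intensity <= 255.0:
            raise SimulationError("mean_intensity must lie in [0, 255]")
        if self.speckle_contrast < 0:
            raise SimulationError("speckle_contrast must be >= 0")
        if self.correlation_length_lateral < 1:
            raise SimulationError("lateral correlation length must be >= 1 pixel")
        if self.correlation_length_axial <= 0:
            raise SimulationError("axial correlation length must be positive")


def default_class_params() -> dict[str, SpeckleParams]:
    """Grade-to-speckle mapping used throughout the package.

    Contrast doubles from each grade to the next and the lateral
    correlation length grows alongside, so the four grades are
    statistically separable yet overlap in any single local statistic.
    """
    return {
        "A": SpeckleParams(120.0, 0.10, 1.0, 1.5),
        "B": SpeckleParams(120.0, 0.20, 1.5, 2.5),
        "C": SpeckleParams(120.0, 0.40, 2.0, 4.0),
        "D": SpeckleParams(120.0, 0.80, 3.0, 6.0),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Geometry and noise configuration for one synthetic B-scan.

    The bright band follows the quadratic surface
    ``row(col) = surface_apex_row + surface_curvature * (col - width/2)**2``
    (row 0 is the shallowest depth) and extends ``nacre_thickness`` rows
    below it.  Pixels outside the band are folded-normal background
    noise with scale ``background_noise_sigma``.
    """

    image_height: int = 512
    image_width: int = 512
    surface_apex_row: int = 140
    surface_curvature: float = 5e-4
    nacre_thickness: int = 220
    background_noise_sigma: float = 4.0
    class_params: Mapping[str, SpeckleParams] = field(default_factory=default_class_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise SimulationError("image dimensions must be positive")
        if self.surface_apex_row + self.nacre_thickness >= self.image_height:
            raise SimulationError(
                "surface_apex_row + nacre_thickness must fit inside the image"
            )
        if set(self.class_params) != set(GRADES):
            raise SimulationError(f"class_params must map exactly the labels {GRADES}")


@dataclass
class LabeledDataset:
    """A reproducible set of synthetic B-scans with luster labels."""

    images: list[np.ndarray]
    labels: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise SimulationError("images and labels must have equal length")
        bad = set(self.labels) - set(GRADES)
        if bad:
            raise SimulationError(f"unknown labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.images)


def surface_rows(cfg: SynthConfig) -> np.ndarray:
    """Integer surface row per column of the quadratic nacre surface."""
    cols = np.arange(cfg.image_width, dtype=float)
    rows = cfg.surface_apex_row + cfg.surface_curvature * (cols - cfg.image_width / 2.0) ** 2
    return np.round(rows).astype(int)


def band_mask(cfg: SynthConfig) -> np.ndarray:
    """Boolean mask of the nacre band (True inside the band)."""
    top = surface_rows(cfg)
    rr = np.arange(cfg.image_height)[:, None]
    return (rr >= top[None, :]) & (rr < (top + cfg.nacre_thickness)[None, :])


def _gaussian_weights(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def _speckle_field(
    shape: tuple[int, int], params: SpeckleParams, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean correlated multiplicative field with std = speckle_contrast."""
    if params.speckle_contrast == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    sig = (params.correlation_length_axial, params.correlation_length_lateral)
    g = ndi.gaussian_filter(white, sigma=sig, mode="wrap")
    # restore unit variance lost to low-pass filtering, then scale to the
    # log-variance that yields the requested std/mean after exponentiation
    w_ax = _gaussian_weights(sig[0])
    w_lat = _gaussian_weights(sig[1])
    atten = np.sqrt(np.sum(w_ax**2) * np.sum(w_lat**2))
    g /= atten
    log_sigma = np.sqrt(np.log1p(params.speckle_contrast**2))
    g *= log_sigma
    return np.exp(g - 0.5 * log_sigma**2)


def generate_bscan(
    cfg: SynthConfig,
    label: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate one synthetic 8-bit B-scan for the given luster grade.

    Returns a ``(image_height, image_width)`` uint8 array; row 0 is the
    shallowest depth.  When *rng* is omitted, a generator seeded from
    ``cfg.seed`` is used, so identical ``(cfg, label)`` give identical
    images.
    """
    if label not in cfg.class_params:
        raise SimulationError(f"unknown luster label {label!r}; expected one of {GRADES}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    params = cfg.class_params[label]

    h, w = cfg.image_height, cfg.image_width
    img = np.abs(rng.normal(0.0, cfg.background_noise_sigma, size=(h, w))) if (
        cfg.background_noise_sigma > 0
    ) else np.zeros((h, w))

    top = surface_rows(cfg)
    mask = band_mask(cfg)
    depth = np.arange(h)[:, None] - top[None, :]  # rows below the surface
    signal = params.mean_intensity * np.exp(-params.depth_decay * np.clip(depth, 0, None))
    speckle = _speckle_field((h, w), params, rng)
    img = np.where(mask, signal * speckle, img)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_dataset(
    cfg: SynthConfig, n_per_class: int, seed: int
) -> LabeledDataset:
    """Generate ``4 * n_per_class`` labeled B-scans, ``n_per_class`` per grade.

    Per-image random streams are spawned from *seed*, so the same
    ``(cfg, seed)`` pair yields a bit-identical dataset.
    """
    if n_per_class < 1:
        raise SimulationError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4 * n_per_class)
    images: list[np.ndarray] = []
    labels: list[str] = []
    i = 0
    for grade in GRADES:
        for _ in range(n_per_class):
            rng = np.random.default_rng(children[i])
            images.append(generate_bscan(cfg, grade, rng=rng))
            labels.append(grade)
            i += 1
    return LabeledDataset(images=images, labels=labels, seed=seed)


def save_dataset(
    dataset: LabeledDataset,
    out_dir: str | Path,
    cfg: SynthConfig,
    fmt: str = "png",
) -> Path:
    """Write images plus a manifest CSV; returns the manifest path.

    The manifest records filename, label, the dataset seed and the full
    SpeckleParams used for each image, so a run can be audited or
    regenerated.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    fields = [
        "filename",
        "label",
        "seed",
        "mean_intensity",
        "speckle_contrast",
        "correlation_length_axial",
        "correlation_length_lateral",
        "depth_decay",
    ]
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
            name = f"bscan_{i:04d}_{label}.{fmt}"
            if fmt == "tiff":
                import tifffile

                tifffile.imwrite(out / name, img)
            else:
                Image.fromarray(img, mode="L").save(out / name)
            p = cfg.class_params[label]
            writer.writerow(
                {
                    "filename": name,
                    "label": label,
                    "seed": dataset.seed,
                    "mean_intensity": p.mean_intensity,
                    "speckle_contrast": p.speckle_contrast,
                    "correlation_length_axial": p.correlation_length_axial,
                    "correlation_length_lateral": p.correlation_length_lateral,
                    "depth_decay": p.depth_decay,
                }
            )
    return manifest


def contrast_ladder(base: SynthConfig, contrasts: Sequence[float]) -> SynthConfig:
    """Replace the per-grade speckle contrasts, keeping everything else."""
    if len(contrasts) != 4:
        raise SimulationError("need one contrast per grade")
    new = {
        g: replace(base.class_params[g], speckle_contrast=c)
        for g, c in zip(GRADES, contrasts)
    }
    return replace(base, class_params=new)
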