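"""End-to-end orchestration: simulate -> preprocess -> extract -> grade.

Each stage reads and writes plain files (PNG/TIFF images, CSV tables,
JSON reports) so runs are auditable; a :class:`RunManifest` records the
configuration snapshot, per-stage output checksums, timestamps and the
seeds, which is sufficient to re-execute a run bit-identically for the
deterministic stages.  All randomness flows from one root seed expanded
per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    GaborConfig,
    GlcmConfig,
    HogConfig,
    LbpConfig,
    assemble_features,
    feature_names,
)
from .grading import (
    FeatureTable,
    LusterGrader,
    SearchSpace,
    SplitSpec,
    sequential_select,
)
from .preprocess import BScan, load_bscan, locate_roi
from .simulate import (
    SpeckleParams,
    SynthConfig,
    default_class_params,
    generate_dataset,
    save_dataset,
)

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline", "stage_names"]

STAGES = ("simulate", "preprocess", "extract", "train", "reduce", "select")


class PipelineError(RuntimeError):
    """A pipeline stage failed or its inputs are missing."""


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented defaults.

    Round-trips losslessly through YAML (:meth:`to_yaml` /
    :meth:`from_yaml`).
    """

    # simulate
    n_per_class: int = 29                  # 4 x 29 = 116 images
    image_format: str = "png"
    synth: dict[str, Any] = field(default_factory=dict)   # SynthConfig overrides
    class_params: dict[str, dict[str, float]] | None = None
    # preprocess
    poly_degree: int = 2                   # quadratic surface model
    target_row: int = 20                   # flattened surface row
    roi_offset: int = 2                    # ROI top edge below the surface line
    canny_sigma: float = 2.0
    # extract
    glcm_gray_levels: int = 16
    # train
    model_kinds: tuple[str, ...] = ("svm", "rfc")
    n_runs: int = 10
    search_iterations: int = 200           # raise (e.g. 50000) for exhaustive searches
    cv_folds: int = 5
    train_fraction: float = 0.8
    # reduce / select
    pca_components: int = 6
    select_fraction: float | None = None   # e.g. 0.2 enables the SFS stage
    # plumbing
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "preprocess", "extract", "train")

    def synth_config(self) -> SynthConfig:
        params = None
        if self.class_params is not None:
            params = {g: SpeckleParams(**p) for g, p in self.class_params.items()}
        kwargs = dict(self.synth)
        if params is not None:
            kwargs["class_params"] = params
        kwargs.setdefault("seed", self.seed)
        return SynthConfig(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["model_kinds"] = list(self.model_kinds)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "model_kinds" in d:
            d["model_kinds"] = tuple(d["model_kinds"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict[str, Any]
    version: str
    seeds: dict[str, int]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    complete: bool = False

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.stages[stage] = {
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["config"]["model_kinds"] = list(d["config"]["model_kinds"])
        d["config"]["stages"] = list(d["config"]["stages"])
        Path(path).write_text(json.dumps(d, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def stage_names() -> tuple[str, ...]:
    return STAGES


def _stage_seeds(root: int) -> dict[str, int]:
    state = np.random.SeedSequence(root).generate_state(len(STAGES)) % (2**31)
    return {s: int(v) for s, v in zip(STAGES, state)}


def simulate_stage(cfg: RunConfig, out_dir: Path, seed: int) -> dict[str, Path]:
    synth = cfg.synth_config()
    ds = generate_dataset(synth, cfg.n_per_class, seed=seed)
    manifest = save_dataset(ds, out_dir / "images", synth, fmt=cfg.image_format)
    return {"manifest": manifest}


def preprocess_stage(cfg: RunConfig, in_dir: Path, out_dir: Path) -> dict[str, Path]:
    manifest = in_dir / "images" / "manifest.csv"
    if not manifest.exists():
        raise PipelineError(
            "preprocess: missing input from the 'simulate' stage "
            f"(no {manifest})"
        )
    df = pd.read_csv(manifest)
    roi_dir = out_dir / "rois"
    roi_dir.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    records = []
    for _, row in df.iterrows():
        bscan = load_bscan(in_dir / "images" / row["filename"])
        roi, stats, fit = locate_roi(
            bscan,
            degree=cfg.poly_degree,
            target_row=cfg.target_row,
            roi_offset=cfg.roi_offset,
            canny_sigma=cfg.canny_sigma,
        )
        stem = Path(row["filename"]).stem
        roi_path = roi_dir / f"{stem}_roi.png"
        Image.fromarray(roi.pixels.astype(np.uint8), mode="L").save(roi_path)
        sidecar = roi_dir / f"{stem}_roi.json"
        sidecar.write_text(
            json.dumps(
                {
                    "source": row["filename"],
                    "label": row["label"],
                    "threshold": stats.threshold,
                    "poly_coeffs": fit.poly_coeffs.tolist(),
                    "residual_rms": fit.residual_rms,
                    "origin_row": roi.origin_row,
                    "origin_col": roi.origin_col,
                },
                indent=2,
            )
        )
        records.append({"roi": roi_path.name, "label": row["label"], "source": row["filename"]})
    index = out_dir / "roi_index.csv"
    pd.DataFrame(records).to_csv(index, index=False)
    return {"roi_index": index}


def extract_stage(cfg: RunConfig, in_dir: Path, out_dir: Path) -> dict[str, Path]:
    index = in_dir / "roi_index.csv"
    if not index.exists():
        raise PipelineError(
            f"extract: missing input from the 'preprocess' stage (no {index})"
        )
    df = pd.read_csv(index)
    glcm = GlcmConfig(gray_levels=cfg.glcm_gray_levels)
    names = feature_names(glcm=glcm)
    from PIL import Image

    rows = []
    for _, row in df.iterrows():
        roi = np.asarray(Image.open(in_dir / "rois" / row["roi"]).convert("L"))
        fv = assemble_features(roi, glcm=glcm)
        rows.append(list(fv.values) + [row["label"], row["source"]])
    out_dir.mkdir(parents=True, exist_ok=True)
    features_path = out_dir / "features.csv"
    pd.DataFrame(rows, columns=names + ["label", "source_id"]).to_csv(
        features_path, index=False
    )
    return {"features": features_path}


def _load_table(in_dir: Path, stage: str) -> FeatureTable:
    path = in_dir / "features.csv"
    if not path.exists():
        raise PipelineError(f"{stage}: missing input from the 'extract' stage (no {path})")
    return FeatureTable.from_dataframe(pd.read_csv(path))


def train_stage(cfg: RunConfig, in_dir: Path, out_dir: Path, seed: int) -> dict[str, Path]:
    table = _load_table(in_dir, "train")
    space = SearchSpace(iterations=cfg.search_iterations, cv_folds=cfg.cv_folds)
    results = {}
    for kind in cfg.model_kinds:
        for use_pca in (False, True) if "reduce" in cfg.stages else (False,):
            grader = LusterGrader(
                table,
                model_kind=kind,
                use_pca=use_pca,
                n_components=cfg.pca_components,
                split_spec=SplitSpec(cfg.train_fraction, True, seed),
                search_space=space,
            )
            res = grader.fit(n_runs=cfg.n_runs)
            arm = f"{kind}_{'pca' if use_pca else 'all'}"
            results[arm] = res.report.to_dict()
    report = out_dir / "report.json"
    report.write_text(json.dumps(results, indent=2))
    return {"report": report}


def select_stage(cfg: RunConfig, in_dir: Path, out_dir: Path, seed: int) -> dict[str, Path]:
    if cfg.select_fraction is None:
        raise PipelineError("select: set select_fraction in the config")
    table = _load_table(in_dir, "select")
    masks = {}
    for kind in cfg.model_kinds:
        mask = sequential_select(
            table, model_kind=kind, fraction=cfg.select_fraction, seed=seed,
            cv_folds=cfg.cv_folds,
        )
        masks[kind] = mask.to_dict()
    out = out_dir / "mask.json"
    out.write_text(json.dumps(masks, indent=2))
    return {"mask": out}


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute the requested stages in order under one output directory.

    Stage failures abort with the failing stage named; the manifest
    written to ``manifest.json`` flags partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg), version=__version__, seeds=seeds
    )
    try:
        for stage in cfg.stages:
            if stage == "simulate":
                outputs = simulate_stage(cfg, out, seeds[stage])
            elif stage == "preprocess":
                outputs = preprocess_stage(cfg, out, out)
            elif stage == "extract":
                outputs = extract_stage(cfg, out, out)
            elif stage in ("train", "reduce"):
                if stage == "reduce":
                    continue  # folded into train as the PCA arm
                outputs = train_stage(cfg, out, out, seeds["train"])
            elif stage == "select":
                outputs = select_stage(cfg, out, out, seeds["select"])
            else:
                raise PipelineError(f"unknown stage {stage!r}")
            manifest.record(stage, outputs)
        manifest.complete = True
    finally:
        manifest.to_json(out / "manifest.json")
    if not manifest.complete:
        raise PipelineError("pipeline aborted; see manifest.json for completed stages")
    return manifest
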