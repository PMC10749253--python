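"""End-to-end orchestration: simulate -> train -> predict -> quantify ->
evaluate -> stratify, with a JSON run manifest.

All coordinates are 0-based, half-open. Edge tiles that do not fill the
tile size are dropped rather than padded, so cell counts are never inflated
by padding. Rerunning with the same config and seed reproduces every output
byte-identically except manifest timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import segmentation, quantify, evaluate, survival
from .simulate import (CohortSimConfig, PatchSimConfig, StainProfile,
                       simulate_cohort, simulate_dataset, save_patch,
                       patch_basename, write_cohort_csv)
from .types import MARKERS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "predict", "quantify", "evaluate", "stratify")


@dataclass
class RoiTiling:
    source_id: str
    roi_boxes: list          # (x, y, width, height), 0-based, half-open
    tile_size: int = 512


@dataclass
class RunConfig:
    stages: tuple = STAGES
    outdir: str = "truet_run"
    seed: int = 0
    n_patients: int = 12
    patches_per_patient: int = 2
    markers: tuple = MARKERS
    n_institutions: int = 2
    patch: PatchSimConfig = field(default_factory=PatchSimConfig)
    train: segmentation.TrainConfig = field(
        default_factory=segmentation.TrainConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    thresholds: dict = field(default_factory=lambda: dict(
        survival.DEFAULT_THRESHOLDS))
    derive_thresholds: bool = False
    um_per_px: float = 0.25
    min_area_px: int = 4

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        kwargs = dict(payload)
        for key, sub in (("patch", PatchSimConfig),
                         ("train", segmentation.TrainConfig),
                         ("cohort", CohortSimConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        for key in ("stages", "markers"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def default_stain_profiles(n: int, jitter_sd: float = 8.0):
    """Institution profiles: the base stain plus per-institution colour shifts."""
    base = StainProfile(color_jitter_sd=jitter_sd, institution_id="inst0")
    shifts = [(0, 0, 0), (12, -6, 4), (-10, 8, -8), (6, 10, 12)]
    return [
        base.shifted(shifts[i % len(shifts)], institution_id=f"inst{i}")
        for i in range(n)
    ]


def tile_roi(image: np.ndarray, roi_boxes, tile_size: int = 512):
    """Non-overlapping grid tiles within each ROI; partial edge tiles dropped.

    Returns a list of (tile, (x0, y0)) with 0-based, half-open coordinates.
    """
    h, w = image.shape[:2]
    tiles = []
    for (x, y, bw, bh) in roi_boxes:
        if x < 0 or y < 0 or x + bw > w or y + bh > h:
            raise ValueError(f"ROI {(x, y, bw, bh)} outside {w}x{h} image")
        if bw < tile_size or bh < tile_size:
            logger.warning("ROI %s smaller than tile size %d; no tiles",
                           (x, y, bw, bh), tile_size)
        for ty in range(y, y + bh - tile_size + 1, tile_size):
            for tx in range(x, x + bw - tile_size + 1, tile_size):
                tiles.append((image[ty : ty + tile_size, tx : tx + tile_size],
                              (tx, ty)))
    return tiles


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.outputs: dict[str, list] = {}
        self.patches = None
        self.models: dict = {}
        self.density_table = None

    def record(self, stage: str, *paths):
        self.outputs.setdefault(stage, []).extend(str(p) for p in paths)

    # -- stages -----------------------------------------------------------
    def simulate(self):
        cfg = self.config
        patch_cfg = dataclasses.replace(cfg.patch, seed=cfg.seed)
        stains = default_stain_profiles(cfg.n_institutions,
                                        cfg.patch.__dict__.get("jitter_sd", 8.0))
        self.patches = simulate_dataset(patch_cfg, stains, cfg.n_patients,
                                        cfg.patches_per_patient, cfg.markers)
        pdir = self.out / "patches"
        pdir.mkdir(exist_ok=True)
        idx: dict = {}
        for patch in self.patches:
            key = (patch.patient_id, patch.marker)
            idx[key] = idx.get(key, -1) + 1
            save_patch(patch, pdir, idx[key])
            stem = patch_basename(patch, idx[key])
            self.record("simulate", pdir / f"{stem}.png",
                        pdir / f"{stem}_mask.png")
        cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seed + 1,
                                         n_patients=cfg.n_patients)
        cohort = simulate_cohort(cohort_cfg)
        write_cohort_csv(cohort, self.out / "cohort.csv")
        self.record("simulate", self.out / "cohort.csv")

    def train(self):
        cfg = self.config
        mdir = self.out / "models"
        mdir.mkdir(exist_ok=True)
        for marker in cfg.markers:
            subset = [p for p in self.patches if p.marker == marker]
            tr, va, _ = segmentation.split_by_patient(
                subset, cfg.train.split_ratios, cfg.seed)
            model = segmentation.build_model(marker, cfg.train)
            segmentation.train(model, tr, va, cfg.train)
            ckpt = mdir / f"{marker}.npz"
            segmentation.save_model(model, ckpt)
            log = mdir / f"{marker}_log.csv"
            pd.DataFrame(model.history).to_csv(log, index=False)
            self.models[marker] = model
            self.record("train", ckpt, log)

    def predict(self):
        cfg = self.config
        outdir = self.out / "pred_masks"
        outdir.mkdir(exist_ok=True)
        idx: dict = {}
        self.pred_masks = {}
        for patch in self.patches:
            model = self.models.get(patch.marker)
            if model is None:
                continue
            key = (patch.patient_id, patch.marker)
            idx[key] = idx.get(key, -1) + 1
            mask = segmentation.predict_mask(
                model, patch.image, cfg.train.binarize_threshold,
                input_size=cfg.train.input_size_px)
            self.pred_masks.setdefault(key, []).append(mask)
            path = outdir / f"{key[0]}_{key[1]}_{idx[key]}_mask.png"
            Image.fromarray(mask * 255).save(path)
            self.record("predict", path)

    def quantify(self):
        cfg = self.config
        source = getattr(self, "pred_masks", None)
        if not source:     # no trained models: count on ground-truth masks
            source = {}
            for patch in self.patches:
                source.setdefault((patch.patient_id, patch.marker),
                                  []).append(patch.mask)
        self.density_table = quantify.quantify_cohort(
            source, cfg.um_per_px, cfg.min_area_px)
        path = self.out / "densities.csv"
        self.density_table.to_csv(path, index=False)
        self.record("quantify", path)

    def evaluate(self):
        if not self.models:
            logger.warning("no trained models; skipping evaluation")
            return
        table = evaluate.evaluate_split(
            self.models, self.patches, self.config.train.binarize_threshold,
            input_size=self.config.train.input_size_px)
        path = self.out / "metrics.csv"
        table.to_csv(path, index=False)
        self.record("evaluate", path)

    def stratify(self):
        cfg = self.config
        cohort = pd.read_csv(self.out / "cohort.csv", dtype={"patient_id": str})
        if self.density_table is not None and len(self.density_table):
            wide = quantify.densities_wide(self.density_table)
            clinical = cohort.drop(
                columns=[c for c in cohort.columns if c.endswith("_density")])
            cohort = clinical.merge(wide, on="patient_id", how="inner")
        if cfg.derive_thresholds:
            thr = survival.derive_thresholds(cohort)
        else:
            thr = survival.ThresholdSet(**cfg.thresholds)
        result = survival.stratify(cohort, thr)
        report = {
            "thresholds": result.thresholds,
            "group_sizes": result.group_sizes,
            "logrank_statistic": result.logrank_statistic,
            "logrank_p": result.logrank_p,
            "n_undetermined": result.n_undetermined,
            "flags": result.flags,
            "status": result.status.to_dict(),
        }
        rpath = self.out / "stratification.json"
        rpath.write_text(json.dumps(report, indent=2))
        rows = [
            {"group": g, "time": t, "survival": s}
            for g, (ts, ss) in sorted(result.km_curves.items())
            for t, s in zip(ts, ss)
        ]
        kpath = self.out / "km_curves.csv"
        pd.DataFrame(rows).to_csv(kpath, index=False)
        self.record("stratify", rpath, kpath)
        if result.logrank_p is not None and len(cohort["event"].unique()) > 1:
            cph = survival.fit_cox(cohort, thr, status=result.status)
            summary = cph.summary.reset_index()[
                ["covariate", "coef", "exp(coef)",
                 "coef lower 95%", "coef upper 95%"]]
            cpath = self.out / "cox_summary.csv"
            summary.to_csv(cpath, index=False)
            self.record("stratify", cpath)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write the run manifest."""
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run = _Run(config)
    ordered = [s for s in STAGES if s in config.stages]
    if ordered and ordered[0] != "simulate":
        raise ValueError("pipeline currently requires the simulate stage")
    for stage in ordered:
        t0 = _time.time()
        try:
            getattr(run, stage)()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs seed=%d", stage,
                    _time.time() - t0, config.seed)
    manifest = {
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "stages": ordered,
        "config": json.loads(json.dumps(dataclasses.asdict(config),
                                        default=str)),
        "outputs": {
            stage: {Path(p).name: _sha256(Path(p)) for p in paths}
            for stage, paths in run.outputs.items()
        },
    }
    mpath = Path(config.outdir) / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
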