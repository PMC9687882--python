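"""End-to-end pipeline: simulate → preprocess → train → segment → calibrate →
quantify → evaluate, over a directory workspace.

The pipeline is the glue for the library stages; each stage reads the
artifacts the previous one wrote and fails with a :class:`DependencyError`
naming the missing upstream stage. All randomness derives from
``RunConfig.seed``, and identical configurations produce byte-identical
result JSON.

The nominal superpixel count refers to a 512x512 frame; smaller frames keep
the same superpixel *density* (count scaled by pixel area), so the default
of 2500 superpixels remains meaningful on reduced test images.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DependencyError
from .io import (read_curve, read_labels, read_mask, read_phantom_csv,
                 read_slice, write_curve, write_labels, write_mask,
                 write_phantom_csv, write_results, write_slice)
from .metrics import dice_coefficient
from .network import UNetSegmenter, predict_mask
from .network.checkpoint import load_model, save_model
from .quantify import IntensityCalibration, fat_volume
from .superpixel import LSCParams, lsc_segment, schematic_map, _summaries
from .synthetic import generate_phantom_series, generate_stack
from .types import SuperpixelMap

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "segment", "calibrate",
          "quantify", "evaluate")

NOMINAL_FRAME = 512  # frame size the nominal superpixel count refers to


@dataclass
class RunConfig:
    """Configuration of one pipeline run. Defaults follow the protocol
    constants: 2500 superpixels, r = 0.25, 20 epochs, erosion kernel 5,
    slice thickness 3 mm, MR-opsy band 1-20%."""

    out_dir: str = "panfat_run"
    seed: int = 0
    log_level: str = "INFO"
    # synthetic study
    n_subjects: int = 4
    shape: tuple = (64, 64)
    spacing: float = 1.0
    thickness: float = 3.0
    fat_fraction: float = 8.0
    noise_sd: float = 1.5
    n_slices: int | None = 3
    confounders: bool = True
    # superpixel preprocessing
    n_superpixels: int = 2500
    r: float = 0.25
    br_tolerance: int = 2
    lsc_max_iter: int = 10
    min_region_fraction: float = 0.25
    # network
    depth: int = 2
    base_channels: int = 8
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss: str = "dice"
    predict_mode: str = "centered"
    # quantification
    kernel_size: int = 5
    low: float = 1.0
    high: float = 20.0
    denominator: str = "full"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        return d

    def effective_superpixels(self) -> int:
        h, w = self.shape
        k = int(round(self.n_superpixels * (h * w) / NOMINAL_FRAME**2))
        return max(16, min(k, h * w // 4))


def _index_path(out: Path) -> Path:
    return out / "index.json"


def _load_index(out: Path, needed_by: str) -> dict:
    p = _index_path(out)
    if not p.exists():
        raise DependencyError(f"stage '{needed_by}' needs artifacts from "
                              f"stage 'simulate' (missing {p.name})")
    return json.loads(p.read_text())


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the requested stages in order; returns per-stage artifacts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        logger.info("stage %s: start (seed=%d, out=%s)", stage, config.seed, out)
        results[stage] = _DISPATCH[stage](config, out)
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return results


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    phantom = generate_phantom_series(seed=config.seed)
    write_phantom_csv(phantom, out / "phantom.csv")
    rng = np.random.default_rng(config.seed)
    index = {"spacing": config.spacing, "thickness": config.thickness,
             "subjects": []}
    for s in range(config.n_subjects):
        sub = f"sub{s:02d}"
        sdir = out / "subjects" / sub
        sdir.mkdir(parents=True, exist_ok=True)
        stack = generate_stack(n_slices=config.n_slices, thickness=config.thickness,
                               shape=tuple(config.shape), spacing=config.spacing,
                               fat_fraction=config.fat_fraction,
                               confounders=config.confounders,
                               noise_sd=config.noise_sd,
                               seed=int(rng.integers(0, 2**31 - 1)))
        rec = {"subject": sub, "slices": [],
               "true_volume_mm3": stack.true_volume_mm3,
               "true_fat_volume_mm3": stack.true_fat_volume_mm3}
        for i, pair in enumerate(stack.slices):
            w = write_slice(pair.water, sdir / f"slice{i:02d}_water.nii")
            f = write_slice(pair.fat, sdir / f"slice{i:02d}_fat.nii")
            m = write_mask(pair.gt_mask, sdir / f"slice{i:02d}_mask.nii",
                           config.spacing, config.thickness)
            rec["slices"].append({"index": i, "water": str(w.relative_to(out)),
                                  "fat": str(f.relative_to(out)),
                                  "mask": str(m.relative_to(out))})
        index["subjects"].append(rec)
    _index_path(out).write_text(json.dumps(index, indent=2, sort_keys=True))
    return index


def _iter_slices(index: dict):
    for rec in index["subjects"]:
        for sl in rec["slices"]:
            yield rec["subject"], sl


def _stage_preprocess(config: RunConfig, out: Path) -> dict:
    index = _load_index(out, "preprocess")
    params = LSCParams(n_superpixels=config.effective_superpixels(), r=config.r,
                       max_iter=config.lsc_max_iter,
                       min_region_fraction=config.min_region_fraction)
    written = []
    for sub, sl in _iter_slices(index):
        water = read_slice(out / sl["water"], phase="water")
        spmap = lsc_segment(water, params)
        schem = schematic_map(water, spmap)
        pdir = out / "preproc" / sub
        pdir.mkdir(parents=True, exist_ok=True)
        lp = write_labels(spmap.labels, pdir / f"slice{sl['index']:02d}_labels.nii",
                          config.spacing, config.thickness)
        sp = write_slice(type(water)(schem.values, water.spacing, water.thickness,
                                     "water"), pdir / f"slice{sl['index']:02d}_schematic.nii")
        sl["labels"] = str(lp.relative_to(out))
        sl["schematic"] = str(sp.relative_to(out))
        written.append(sl["labels"])
    _index_path(out).write_text(json.dumps(index, indent=2, sort_keys=True))
    return {"n_slices": len(written)}


def _require_preprocessed(index: dict, stage: str) -> None:
    for _, sl in _iter_slices(index):
        if "schematic" not in sl:
            raise DependencyError(
                f"stage '{stage}' needs artifacts from stage 'preprocess'")


def _stage_train(config: RunConfig, out: Path) -> dict:
    index = _load_index(out, "train")
    _require_preprocessed(index, "train")
    subjects = sorted(rec["subject"] for rec in index["subjects"])
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(subjects))
    n_val = max(1, int(round(0.2 * len(subjects))))
    val_subjects = {subjects[i] for i in order[:n_val]}
    xs, ys, xv, yv = [], [], [], []
    for sub, sl in _iter_slices(index):
        img = read_slice(out / sl["schematic"]).data
        mask = read_mask(out / sl["mask"])
        (xv if sub in val_subjects else xs).append(img)
        (yv if sub in val_subjects else ys).append(mask)
    est = UNetSegmenter(depth=config.depth, base_channels=config.base_channels,
                        input_size=config.shape[0], epochs=config.epochs,
                        batch_size=config.batch_size,
                        learning_rate=config.learning_rate, loss=config.loss,
                        seed=config.seed)
    est.fit(xs, ys, X_val=xv, y_val=yv)
    ckpt = save_model(est.model_, out / "model.npz")
    hist = pd.DataFrame({"epoch": np.arange(1, len(est.history_) + 1),
                         "train_dice": est.history_.train_dice,
                         "val_dice": est.history_.val_dice})
    hist.to_csv(out / "train_history.csv", index=False)
    return {"checkpoint": str(ckpt), "final_val_dice": est.history_.val_dice[-1],
            "val_subjects": sorted(val_subjects)}


def _stage_segment(config: RunConfig, out: Path) -> dict:
    index = _load_index(out, "segment")
    _require_preprocessed(index, "segment")
    ckpt = out / "model.npz"
    if not ckpt.exists():
        raise DependencyError("stage 'segment' needs artifacts from stage 'train'")
    model = load_model(ckpt)
    for sub, sl in _iter_slices(index):
        schem = read_slice(out / sl["schematic"]).data
        labels = read_labels(out / sl["labels"])
        k, centers, sizes = _summaries(labels)
        spmap = SuperpixelMap(labels=labels, K_actual=k, centers=centers, sizes=sizes)
        pred = predict_mask(model, schem, spmap, mode=config.predict_mode)
        pdir = out / "predictions" / sub
        pdir.mkdir(parents=True, exist_ok=True)
        mp = write_mask(pred.mask, pdir / f"slice{sl['index']:02d}_pred.nii",
                        config.spacing, config.thickness)
        sl["pred"] = str(mp.relative_to(out))
    _index_path(out).write_text(json.dumps(index, indent=2, sort_keys=True))
    return {"mode": config.predict_mode}


def _stage_calibrate(config: RunConfig, out: Path) -> dict:
    csv = out / "phantom.csv"
    if not csv.exists():
        raise DependencyError("stage 'calibrate' needs artifacts from stage 'simulate'")
    df = read_phantom_csv(csv)
    est = IntensityCalibration().fit(df["mean_intensity"], df["fraction_pct"])
    write_curve(est.to_curve(), out / "curve.json")
    return {"slope": est.slope_, "intercept": est.intercept_,
            "r_squared": est.r_squared_}


def _stage_quantify(config: RunConfig, out: Path) -> dict:
    index = _load_index(out, "quantify")
    curve_path = out / "curve.json"
    if not curve_path.exists():
        raise DependencyError("stage 'quantify' needs artifacts from stage 'calibrate'")
    curve = read_curve(curve_path)
    quants = {}
    for rec in index["subjects"]:
        fats, masks = [], []
        for sl in rec["slices"]:
            if "pred" not in sl:
                raise DependencyError(
                    "stage 'quantify' needs artifacts from stage 'segment'")
            fats.append(read_slice(out / sl["fat"], phase="fat"))
            masks.append(read_mask(out / sl["pred"]))
        result = fat_volume(fats, masks, curve, spacing=config.spacing,
                            thickness=config.thickness,
                            kernel_size=config.kernel_size,
                            low=config.low, high=config.high,
                            denominator=config.denominator)  # type: ignore[arg-type]
        write_results(result, out / "results" / rec["subject"],
                      config=config.to_dict())
        quants[rec["subject"]] = result
    return quants


def _stage_evaluate(config: RunConfig, out: Path) -> dict:
    index = _load_index(out, "evaluate")
    rows = []
    for sub, sl in _iter_slices(index):
        if "pred" not in sl:
            raise DependencyError(
                "stage 'evaluate' needs artifacts from stage 'segment'")
        pred = read_mask(out / sl["pred"])
        gt = read_mask(out / sl["mask"])
        if pred.any() or gt.any():
            rows.append({"subject": sub, "slice": sl["index"],
                         "dsc": dice_coefficient(pred, gt)})
    df = pd.DataFrame(rows)
    df.to_csv(out / "evaluation.csv", index=False)
    mean = float(df["dsc"].mean()) if len(df) else float("nan")
    return {"mean_dsc": mean, "n": len(df)}


_DISPATCH = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "segment": _stage_segment,
    "calibrate": _stage_calibrate,
    "quantify": _stage_quantify,
    "evaluate": _stage_evaluate,
}
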