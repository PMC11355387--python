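"""End-to-end experiment orchestration.

``run_experiment`` drives the whole study on synthetic data: simulate
scenes, build the tiled/augmented dataset, train each requested
architecture, segment the held-out orthomosaics, and quantify vegetation
cover against the synthetic truth — writing reports (CSV + JSON), masks and
overlays (PNG), training histories, and a run log with seeds and a
configuration hash.

Configuration is a plain nested dict (typically loaded from YAML); see
``default_config`` for the full schema with defaults.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .field import generate_scenes
from .io import save_image, save_mask, scene_params_from_dict
from .metrics import (AreaReport, build_area_report, count_foreground,
                      iou as mask_iou, rmse)
from .models import ModelSpec, build_model
from .mosaic import overlay, segment_orthomosaic
from .tiling import build_dataset, split_into_quadrants
from .training import TrainConfig, train, _evaluate, _tiles_to_arrays

ARCH_LABELS = {"unet": "UNet", "deeplabv3plus": "DeepLabV3+",
               "unet_xception": "UNet Style Xception"}


def default_config() -> dict:
    """Desk-scale defaults: a complete run in minutes on one CPU."""
    return {
        "seed": 0,
        "scene": {
            "width_px": 800, "height_px": 448,
            "n_rows": 4, "plants_per_row": 8,
            "paddle_axis_px": [8.0, 24.0],
        },
        "n_scenes": 40,
        "split": {"train_fraction": 0.65, "val_fraction": 0.15},
        "model": {"input_size": 160, "base_filters": 16, "depth": 3,
                  "atrous_rates": [1, 6, 12, 18]},
        "architectures": ["unet", "deeplabv3plus", "unet_xception"],
        "train": {"epochs": 2, "batch_size": 8, "learning_rate": 2e-3},
        "threshold": 0.5,
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _tile_eval(model, tiles, batch_size, threshold):
    """Tile-level metrics on held-out tiles at model resolution: pooled IoU
    plus RMSE over per-tile foreground pixel counts (predicted vs truth)."""
    imgs, masks = _tiles_to_arrays(tiles)
    _, pooled_iou = _evaluate(model, imgs, masks, batch_size, threshold)
    pred_counts, true_counts = [], []
    for i in range(0, len(imgs), batch_size):
        probs = model.predict_batch(imgs[i:i + batch_size])
        pred = probs >= threshold
        pred_counts.extend(pred.sum(axis=(1, 2)).tolist())
        true_counts.extend(masks[i:i + batch_size].sum(axis=(1, 2)).tolist())
    return {"iou": pooled_iou,
            "rmse_px": rmse(true_counts, pred_counts),
            "n_tiles": len(tiles)}


def run_experiment(config: dict | None = None, out_dir=None,
                   progress=print) -> tuple[AreaReport, dict, dict]:
    """Run the full simulate -> tile -> train -> segment -> quantify study.

    Returns ``(area_report, histories, log)``.  The area report is the
    orthomosaic-level comparison table (one row per architecture plus the
    reference row) for the first held-out scene; tile-level metrics over
    all held-out tiles and mosaic metrics for every held-out scene are in
    the log.  Fully reproducible: every random stream derives from
    ``config['seed']``.
    """
    cfg = _merge(default_config(), config or {})
    seed = int(cfg["seed"])
    t_start = time.time()
    timings: dict[str, float] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: simulate ---------------------------------------------
    t0 = time.time()
    try:
        base = scene_params_from_dict(cfg["scene"])
        scenes = generate_scenes(base, int(cfg["n_scenes"]), seed=seed * 1000 + 1)
    except Exception as exc:
        raise ConfigurationError(f"[simulate] {exc}") from exc
    timings["simulate_s"] = time.time() - t0

    # --- stage 2: dataset ----------------------------------------------
    t0 = time.time()
    try:
        split = build_dataset(
            scenes, cfg["split"]["train_fraction"],
            cfg["split"]["val_fraction"], seed=seed * 1000 + 2,
            model_size=int(cfg["model"]["input_size"]))
    except Exception as exc:
        raise ConfigurationError(f"[dataset] {exc}") from exc
    timings["dataset_s"] = time.time() - t0
    progress(f"dataset: {split.accounting}")

    test_scenes = [s for s in scenes if s[0].id in set(split.test_sources)]
    if not test_scenes:
        raise ConfigurationError("[dataset] no held-out scenes to evaluate")

    # --- stage 3+4: train + segment held-out mosaics --------------------
    histories: dict[str, dict] = {}
    tile_metrics: dict[str, dict] = {}
    mosaic_metrics: dict[str, list] = {}
    predictions: dict[str, object] = {}
    per_tile_counts: dict[str, tuple] = {}
    ref_image, ref_mask, ref_scene = test_scenes[0]
    ref_tile_counts = [int(t.native_mask.sum()) for t in
                       split_into_quadrants(ref_image, ref_mask)]
    threshold = float(cfg["threshold"])

    for arch in cfg["architectures"]:
        label = ARCH_LABELS.get(arch, arch)
        t0 = time.time()
        try:
            spec = ModelSpec(architecture=arch, seed=seed * 1000 + 3,
                             input_size=int(cfg["model"]["input_size"]),
                             base_filters=int(cfg["model"]["base_filters"]),
                             depth=int(cfg["model"]["depth"]),
                             atrous_rates=tuple(cfg["model"]["atrous_rates"]))
            model = build_model(spec)
            tcfg = TrainConfig(seed=seed * 1000 + 4, threshold=threshold,
                               **{k: v for k, v in cfg["train"].items()})
            model, hist = train(model, split, tcfg)
        except Exception as exc:
            raise ConfigurationError(f"[train:{arch}] {exc}") from exc
        timings[f"train_{arch}_s"] = time.time() - t0
        histories[arch] = dataclasses.asdict(hist)
        progress(f"{label}: best val IoU {hist.best_val_iou:.3f} "
                 f"(epoch {hist.best_epoch}) in {timings[f'train_{arch}_s']:.0f}s")

        try:
            tile_metrics[arch] = _tile_eval(model, split.test_tiles,
                                            tcfg.batch_size, threshold)
            mosaic_metrics[arch] = []
            for image, mask, scene in test_scenes:
                pred = segment_orthomosaic(model, image, threshold)
                mosaic_metrics[arch].append({
                    "scene_id": image.id,
                    "iou": mask_iou(pred.full_mask, mask),
                    "pixel_count": count_foreground(pred.full_mask),
                    "true_pixel_count": scene.true_foreground_px,
                })
                if image.id == ref_image.id:
                    predictions[label] = pred
                    per_tile_counts[label] = (
                        [int(m.values.sum()) for m in pred.tile_masks],
                        ref_tile_counts)
                    if out_dir is not None:
                        save_mask(pred.full_mask,
                                  out_dir / "masks" / f"{arch}_{image.id}.png")
                        ov = overlay(image, pred.full_mask)
                        save_image(
                            type(image)(ov, image.pixel_area_m2, id="ov"),
                            out_dir / "overlays" / f"{arch}_{image.id}.png")
        except ConfigurationError:
            raise
        except Exception as exc:
            raise ConfigurationError(f"[segment:{arch}] {exc}") from exc

    # --- stage 5: quantify ----------------------------------------------
    try:
        report = build_area_report(predictions, ref_mask,
                                   base.pixel_area_m2, per_tile_counts)
    except Exception as exc:
        raise ConfigurationError(f"[quantify] {exc}") from exc

    log = {
        "seed": seed,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "accounting": split.accounting,
        "reference_scene": ref_image.id,
        "reference_true_area_m2": ref_scene.true_area_m2,
        "tile_metrics": tile_metrics,
        "mosaic_metrics": mosaic_metrics,
        "timings_s": timings,
        "total_s": time.time() - t_start,
    }
    if out_dir is not None:
        report.table.to_csv(out_dir / "report.csv", index=False)
        (out_dir / "report.json").write_text(
            report.table.to_json(orient="records", indent=2))
        (out_dir / "histories.json").write_text(json.dumps(histories, indent=2))
        (out_dir / "log.json").write_text(json.dumps(log, indent=2))
        save_mask(ref_mask, out_dir / "masks" / f"reference_{ref_image.id}.png")
    return report, histories, log
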