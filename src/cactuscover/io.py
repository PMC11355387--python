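"""Disk formats: PNG rasters, JSON sidecars/reports, YAML configuration.

Masks are written as single-band PNGs with values {0, 255} (255 =
vegetation) and read back to {0, 1}; images are plain 3-channel 8-bit PNGs.
Every scene gets a JSON sidecar recording its seed, parameters and exact
ground truth so a directory of scenes is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .errors import InvalidParameterError
from .field import FieldScene, SceneParams
from .types import BinaryMask, OrthoImage


def save_image(image: OrthoImage, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels).save(path)
    return path


def save_mask(mask: BinaryMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((mask.values * 255).astype(np.uint8)).save(path)
    return path


def load_image(path, pixel_area_m2: float, id: str | None = None) -> OrthoImage:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"))
    return OrthoImage(arr, pixel_area_m2, id=id or path.stem)


def load_mask(path, image_id: str | None = None) -> BinaryMask:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise InvalidParameterError(
            f"mask PNG must contain only {{0, 255}} (or {{0, 1}}), got {vals}")
    return BinaryMask((arr > 0).astype(np.uint8), image_id=image_id or path.stem)


def save_scene(out_dir, image: OrthoImage, mask: BinaryMask,
               scene: FieldScene) -> dict:
    """Write image + mask PNGs and a JSON sidecar; returns the file map."""
    out_dir = Path(out_dir)
    stem = image.id
    paths = {
        "image": save_image(image, out_dir / f"{stem}.png"),
        "mask": save_mask(mask, out_dir / f"{stem}_mask.png"),
        "sidecar": out_dir / f"{stem}.json",
    }
    sidecar = {
        "seed": scene.params.seed,
        "params": dataclasses.asdict(scene.params),
        "true_foreground_px": scene.true_foreground_px,
        "true_area_m2": scene.true_area_m2,
        "pixel_area_m2": scene.params.pixel_area_m2,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def scene_params_from_dict(d: dict) -> SceneParams:
    known = {f.name for f in dataclasses.fields(SceneParams)}
    unknown = set(d) - known
    if unknown:
        raise InvalidParameterError(f"unknown scene parameters: {sorted(unknown)}")
    d = dict(d)
    for key in ("paddle_count_range", "paddle_axis_px"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneParams(**d)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidParameterError("configuration must be a YAML mapping")
    return cfg
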