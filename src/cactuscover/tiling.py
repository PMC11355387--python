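"""Quadrant tiling, model-resolution resizing, augmentation, and dataset
assembly.

A parent orthophoto is split into four quadrants (top-left, top-right,
bottom-left, bottom-right; for odd dimensions the top/left quadrants take
the extra pixel), each quadrant is rescaled to a square model resolution
(default 160 x 160: bilinear for images, nearest-neighbour for masks so they
stay binary), and training tiles are expanded four-fold with {identity,
horizontal flip, 90 deg rotation, 180 deg rotation} applied identically to
image and mask.

Splitting is always at the source-image level, never the tile level, so no
parent raster can leak between train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from PIL import Image

from .errors import (AlignmentError, ConfigurationError,
                     InvalidParameterError, ReassemblyError)
from .types import BinaryMask, OrthoImage

AUGMENTATIONS = ("identity", "hflip", "rot90", "rot180")


@dataclass
class TileRecord:
    """One quadrant of a parent raster, at native and/or model resolution."""

    parent_id: str
    quadrant_index: int            # 0 TL, 1 TR, 2 BL, 3 BR
    row_offset: int
    col_offset: int
    native_height: int
    native_width: int
    native_image: np.ndarray | None = None   # (h, w, 3) uint8
    native_mask: np.ndarray | None = None    # (h, w) uint8 {0,1}
    model_image: np.ndarray | None = None    # (s, s, 3) uint8
    model_mask: np.ndarray | None = None     # (s, s) uint8 {0,1}
    augmentation: str = "identity"
    capture_style: str | None = None


@dataclass
class DatasetSplit:
    """Train (augmented) / validation / test tiles plus stage accounting."""

    train_tiles: list
    validation_tiles: list
    test_tiles: list
    split_seed: int
    train_sources: list[str] = field(default_factory=list)
    validation_sources: list[str] = field(default_factory=list)
    test_sources: list[str] = field(default_factory=list)
    accounting: dict = field(default_factory=dict)


def _quadrant_bounds(h: int, w: int):
    """Half-open quadrant boxes; top/left take the extra pixel when odd."""
    h0 = (h + 1) // 2
    w0 = (w + 1) // 2
    return [(0, h0, 0, w0), (0, h0, w0, w), (h0, h, 0, w0), (h0, h, w0, w)]


def split_into_quadrants(image: OrthoImage, mask: BinaryMask) -> list[TileRecord]:
    """Split an aligned image/mask pair into its four quadrant tiles."""
    if image.shape != mask.shape:
        raise AlignmentError(
            f"image {image.shape} and mask {mask.shape} differ")
    h, w = image.shape
    tiles = []
    for q, (r0, r1, c0, c1) in enumerate(_quadrant_bounds(h, w)):
        tiles.append(TileRecord(
            parent_id=image.id, quadrant_index=q,
            row_offset=r0, col_offset=c0,
            native_height=r1 - r0, native_width=c1 - c0,
            native_image=image.pixels[r0:r1, c0:c1].copy(),
            native_mask=mask.values[r0:r1, c0:c1].copy()))
    return tiles


def reassemble_quadrants(tiles) -> tuple[np.ndarray | None, np.ndarray]:
    """Exact inverse of :func:`split_into_quadrants` on native rasters.

    Placement is governed by the recorded offsets, not list order.  Returns
    ``(image, mask)`` arrays; image is None when any tile lacks a native
    image (mask-only reassembly).
    """
    tiles = list(tiles)
    if len(tiles) != 4:
        raise ReassemblyError(f"expected 4 tiles, got {len(tiles)}")
    parent_ids = {t.parent_id for t in tiles}
    if len(parent_ids) != 1:
        raise ReassemblyError(f"tiles from different parents: {parent_ids}")
    if {t.quadrant_index for t in tiles} != {0, 1, 2, 3}:
        raise ReassemblyError("quadrant indices must be exactly {0,1,2,3}")
    for t in tiles:
        if t.native_mask is None:
            raise ReassemblyError("tile lacks a native-resolution mask")
        if t.native_mask.shape != (t.native_height, t.native_width):
            raise ReassemblyError("tile mask does not match its recorded size")
    by_q = {t.quadrant_index: t for t in tiles}
    h = by_q[0].native_height + by_q[2].native_height
    w = by_q[0].native_width + by_q[1].native_width
    expected = _quadrant_bounds(h, w)
    for q, (r0, r1, c0, c1) in enumerate(expected):
        t = by_q[q]
        if (t.row_offset, t.col_offset) != (r0, c0) or \
           (t.native_height, t.native_width) != (r1 - r0, c1 - c0):
            raise ReassemblyError(f"quadrant {q} offsets/shape inconsistent")
    mask = np.zeros((h, w), dtype=np.uint8)
    have_images = all(t.native_image is not None for t in tiles)
    image = np.zeros((h, w, 3), dtype=np.uint8) if have_images else None
    for q, (r0, r1, c0, c1) in enumerate(expected):
        t = by_q[q]
        mask[r0:r1, c0:c1] = t.native_mask
        if have_images:
            image[r0:r1, c0:c1] = t.native_image
    return image, mask


def _resize_image(arr: np.ndarray, size: tuple[int, int], nearest: bool) -> np.ndarray:
    """PIL-backed resize; ``size`` is (height, width)."""
    resample = Image.NEAREST if nearest else Image.BILINEAR
    out = Image.fromarray(arr).resize((size[1], size[0]), resample)
    return np.asarray(out)


def resize_pair(tile: TileRecord, model_size: int = 160) -> TileRecord:
    """Rescale a tile's native rasters to ``model_size`` squared.

    Image: bilinear.  Mask: nearest-neighbour, so the value set {0,1} is
    preserved exactly.
    """
    if model_size < 8:
        raise InvalidParameterError("model_size must be >= 8")
    if tile.native_image is None or tile.native_mask is None:
        raise InvalidParameterError("resize_pair needs native rasters")
    return replace(
        tile,
        model_image=_resize_image(tile.native_image, (model_size, model_size),
                                  nearest=False),
        model_mask=_resize_image(tile.native_mask, (model_size, model_size),
                                 nearest=True))


def _apply_aug(arr: np.ndarray, aug: str) -> np.ndarray:
    if aug == "identity":
        return arr.copy()
    if aug == "hflip":
        return arr[:, ::-1].copy()
    if aug == "rot90":
        return np.rot90(arr).copy()
    if aug == "rot180":
        return np.rot90(arr, 2).copy()
    raise InvalidParameterError(f"unknown augmentation {aug!r}")


def augment_pair(tile: TileRecord) -> list[TileRecord]:
    """Expand one model-resolution tile into its four augmented variants."""
    if tile.model_image is None or tile.model_mask is None:
        raise InvalidParameterError("augment_pair needs model-resolution rasters")
    s0, s1 = tile.model_mask.shape
    if s0 != s1:
        raise InvalidParameterError(
            "augmentation requires square model rasters (90 deg rotation)")
    out = []
    for aug in AUGMENTATIONS:
        out.append(replace(
            tile, augmentation=aug,
            model_image=_apply_aug(tile.model_image, aug),
            model_mask=_apply_aug(tile.model_mask, aug),
            native_image=None, native_mask=None))
    return out


def tile_scene(image: OrthoImage, mask: BinaryMask, model_size: int = 160,
               keep_native: bool = False, capture_style: str | None = None
               ) -> list[TileRecord]:
    """Split one scene into four model-resolution tiles."""
    tiles = []
    for t in split_into_quadrants(image, mask):
        t = resize_pair(t, model_size)
        if not keep_native:
            t = replace(t, native_image=None, native_mask=None)
        t = replace(t, capture_style=capture_style)
        tiles.append(t)
    return tiles


def build_dataset(scenes: Iterable, train_fraction: float,
                  val_fraction: float = 0.0, seed: int = 0,
                  model_size: int = 160) -> DatasetSplit:
    """Assemble a train/validation/test dataset from scenes.

    ``scenes`` yields ``(OrthoImage, BinaryMask)`` or ``(OrthoImage,
    BinaryMask, FieldScene)`` triples; it may be a generator, since only
    model-resolution tiles are retained (native rasters are dropped after
    resizing so hundreds of full-size parents fit in memory).  Membership is
    decided per source image with a seeded permutation; augmentation (x4) is
    applied to training tiles only.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError("train_fraction must be in (0, 1)")
    if not (0.0 <= val_fraction < 1.0):
        raise ConfigurationError("val_fraction must be in [0, 1)")
    if train_fraction + val_fraction >= 1.0:
        raise ConfigurationError("train_fraction + val_fraction must be < 1")

    per_scene_tiles: list[list[TileRecord]] = []
    source_ids: list[str] = []
    for item in scenes:
        image, mask = item[0], item[1]
        style = None
        if len(item) > 2 and hasattr(item[2], "params"):
            style = item[2].params.capture_style
        per_scene_tiles.append(tile_scene(image, mask, model_size,
                                          capture_style=style))
        source_ids.append(image.id)
    n = len(per_scene_tiles)
    if n == 0:
        raise ConfigurationError("no scenes supplied")
    if len(set(source_ids)) != n:
        raise ConfigurationError("scene ids must be unique")

    n_train = int(round(train_fraction * n))
    n_val = int(round(val_fraction * n))
    n_test = n - n_train - n_val
    if n_train < 1 or n_test < 1 or (val_fraction > 0 and n_val < 1):
        raise ConfigurationError(
            f"cannot populate every split from {n} scenes "
            f"(train {n_train}, val {n_val}, test {n_test})")

    order = np.random.default_rng(seed).permutation(n)
    train_idx = order[:n_train]
    val_idx = order[n_train:n_train + n_val]
    test_idx = order[n_train + n_val:]

    train_tiles: list[TileRecord] = []
    for i in train_idx:
        for t in per_scene_tiles[i]:
            train_tiles.extend(augment_pair(t))
    val_tiles = [t for i in val_idx for t in per_scene_tiles[i]]
    test_tiles = [t for i in test_idx for t in per_scene_tiles[i]]

    accounting = {
        "source_images": n,
        "train_sources": int(n_train),
        "validation_sources": int(n_val),
        "test_sources": int(n_test),
        "train_tiles": int(n_train * 4),
        "augmented": len(train_tiles),
        "validation_tiles": len(val_tiles),
        "test_tiles": len(test_tiles),
    }
    return DatasetSplit(
        train_tiles=train_tiles, validation_tiles=val_tiles,
        test_tiles=test_tiles, split_seed=seed,
        train_sources=[source_ids[i] for i in train_idx],
        validation_sources=[source_ids[i] for i in val_idx],
        test_sources=[source_ids[i] for i in test_idx],
        accounting=accounting)
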