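"""Full-orthomosaic inference: tile, predict, binarise, upscale, reassemble.

Images larger than a network's input cannot be segmented directly, so the
mosaic is quadrant-tiled, each quadrant downscaled to model resolution and
predicted, the per-tile probability maps binarised, the binary masks
upscaled (nearest-neighbour) back to the quadrant's native size, and the
four native masks stitched into a mosaic-level mask with exactly the input
dimensions.  Binarising before upscaling keeps every stored mask binary;
mosaics beyond a configurable tile limit are split recursively.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from PIL import Image

from .errors import InvalidParameterError
from .models import ProbabilityMap, SegModel
from .tiling import reassemble_quadrants, resize_pair, split_into_quadrants
from .types import BinaryMask, OrthoImage, check_aligned


@dataclass
class MosaicPrediction:
    full_mask: BinaryMask
    tile_probability_maps: list[ProbabilityMap]
    tile_masks: list[BinaryMask]      # upscaled, native-resolution per tile
    threshold: float
    model_id: str


def binarize(prob: ProbabilityMap | np.ndarray, threshold: float = 0.5
             ) -> BinaryMask:
    """Threshold a probability map; ties (p == threshold) go to foreground."""
    if not (0.0 < threshold < 1.0):
        raise InvalidParameterError("threshold must lie in (0, 1)")
    values = getattr(prob, "values", prob)
    model_id = getattr(prob, "model_id", "prob")
    return BinaryMask((np.asarray(values) >= threshold).astype(np.uint8),
                      image_id=model_id)


def upscale_mask(mask: BinaryMask, target_h: int, target_w: int) -> BinaryMask:
    """Nearest-neighbour upscale of a binary mask to the target size."""
    h, w = mask.shape
    if target_h < h or target_w < w:
        raise InvalidParameterError(
            f"target {(target_h, target_w)} smaller than source {(h, w)}")
    out = Image.fromarray(mask.values).resize((target_w, target_h),
                                              Image.NEAREST)
    return BinaryMask(np.asarray(out), image_id=mask.image_id)


def segment_orthomosaic(model: SegModel, image: OrthoImage,
                        threshold: float = 0.5, *,
                        max_tile_px: int = 2000) -> MosaicPrediction:
    """Segment a full orthomosaic into a same-size binary vegetation mask.

    Pipeline per quadrant: downscale to model resolution (bilinear),
    predict, binarise at ``threshold``, upscale the binary mask back to the
    quadrant's native size (nearest-neighbour), then stitch the quadrants.
    Quadrants still exceeding ``max_tile_px`` on a side are split
    recursively, so arbitrarily large mosaics reduce to model-size tiles.
    """
    h, w = image.shape
    if h < 2 or w < 2:
        raise InvalidParameterError("orthomosaic must be at least 2 x 2")
    prob_maps: list[ProbabilityMap] = []
    tile_masks: list[BinaryMask] = []
    full = _segment_region(model, image.pixels, threshold, max_tile_px,
                           prob_maps, tile_masks)
    return MosaicPrediction(
        full_mask=BinaryMask(full, image_id=image.id),
        tile_probability_maps=prob_maps, tile_masks=tile_masks,
        threshold=threshold, model_id=model.id)


def _segment_region(model, pixels, threshold, max_tile_px, prob_maps,
                    tile_masks) -> np.ndarray:
    h, w = pixels.shape[:2]
    region_img = OrthoImage(pixels, 1.0, id="region")
    region_mask = BinaryMask(np.zeros((h, w), np.uint8), image_id="region")
    tiles = split_into_quadrants(region_img, region_mask)
    out_tiles = []
    for t in tiles:
        if max(t.native_height, t.native_width) > max_tile_px:
            sub = _segment_region(model, t.native_image, threshold,
                                  max_tile_px, prob_maps, tile_masks)
            out_tiles.append(replace(t, native_mask=sub, native_image=None))
            continue
        rt = resize_pair(t, model.spec.input_size)
        probs = model.predict_batch(
            rt.model_image[None].astype(np.float32) / 255.0)[0]
        pm = ProbabilityMap(values=probs, model_id=model.id)
        tile_mask = binarize(pm, threshold)
        if t.native_height >= tile_mask.shape[0] and \
           t.native_width >= tile_mask.shape[1]:
            up = upscale_mask(tile_mask, t.native_height, t.native_width)
        else:  # mosaic smaller than 2x model size: map back down, still nearest
            arr = Image.fromarray(tile_mask.values).resize(
                (t.native_width, t.native_height), Image.NEAREST)
            up = BinaryMask(np.asarray(arr), image_id=tile_mask.image_id)
        prob_maps.append(pm)
        tile_masks.append(up)
        out_tiles.append(replace(t, native_mask=up.values, native_image=None))
    _, mask = reassemble_quadrants(out_tiles)
    return mask


def quantization_floor_mask(mask: BinaryMask, model_size: int = 160, *,
                            max_tile_px: int = 2000) -> BinaryMask:
    """Push the ground-truth mask itself through the tiling pipeline.

    Emulates a perfect model: each quadrant of the truth mask is
    downscaled to model resolution (nearest), then upscaled back and
    reassembled — exactly the resolution round-trip every real prediction
    undergoes.  The difference between this mask's area and the truth area
    is the pipeline's resize-quantisation floor.
    """
    from .tiling import _quadrant_bounds

    def region(values: np.ndarray) -> np.ndarray:
        h, w = values.shape
        out = np.zeros((h, w), np.uint8)
        for (r0, r1, c0, c1) in _quadrant_bounds(h, w):
            sub = values[r0:r1, c0:c1]
            if max(sub.shape) > max_tile_px:
                out[r0:r1, c0:c1] = region(sub)
                continue
            down = Image.fromarray(sub).resize((model_size, model_size),
                                               Image.NEAREST)
            up = down.resize((c1 - c0, r1 - r0), Image.NEAREST)
            out[r0:r1, c0:c1] = np.asarray(up)
        return out

    return BinaryMask(region(mask.values), image_id=mask.image_id)


def overlay(image: OrthoImage, mask: BinaryMask,
            color=(0, 0, 255), blend: float = 0.6) -> np.ndarray:
    """Alpha-blend mask foreground toward ``color`` (default pure blue).

    Background pixels are returned bit-identical to the input.
    """
    check_aligned(image, mask)
    if not (0.0 <= blend <= 1.0):
        raise InvalidParameterError("blend must lie in [0, 1]")
    out = image.pixels.copy()
    fg = mask.values.astype(bool)
    if fg.any():
        base = out[fg].astype(np.float32)
        tint = np.asarray(color, dtype=np.float32)[None, :]
        out[fg] = np.clip(np.round((1.0 - blend) * base + blend * tint),
                          0, 255).astype(np.uint8)
    return out
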