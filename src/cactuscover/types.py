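"""Core raster containers shared across the pipeline.

An :class:`OrthoImage` is an already-mosaicked RGB raster together with the
ground area covered by one pixel (m^2), which is all the georeferencing the
area-quantification pipeline needs.  A :class:`BinaryMask` is a {0,1} raster
aligned with an image; it is either ground truth or a model prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidParameterError


@dataclass
class OrthoImage:
    """8-bit RGB orthophoto plus the ground area of one pixel in m^2."""

    pixels: np.ndarray          # (H, W, 3) uint8
    pixel_area_m2: float
    id: str = "ortho"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidParameterError("OrthoImage.pixels must be H x W x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InvalidParameterError("OrthoImage must be non-empty")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)
        if not (self.pixel_area_m2 > 0):
            raise InvalidParameterError("pixel_area_m2 must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """{0,1} raster; ``image_id`` names the raster it annotates."""

    values: np.ndarray          # (H, W) uint8 in {0, 1}
    image_id: str = "ortho"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise InvalidParameterError("BinaryMask.values must be 2-D")
        if not np.isin(np.unique(v), (0, 1)).all():
            raise InvalidParameterError("BinaryMask values must be 0 or 1")
        self.values = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def foreground_count(self) -> int:
        return int(self.values.sum())


def check_aligned(image: OrthoImage, mask: BinaryMask) -> None:
    if image.shape != mask.shape:
        raise AlignmentError(
            f"image shape {image.shape} != mask shape {mask.shape}")
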