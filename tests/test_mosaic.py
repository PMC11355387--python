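"""Mosaic-level inference: thresholding, mask rescaling, seam-free
reassembly, overlays, and the resize-quantisation floor."""

import numpy as np
import pytest

from cactuscover import (AlignmentError, BinaryMask, InvalidParameterError,
                        OrthoImage, SceneParams, generate_scene)
from cactuscover.models import ModelSpec, ProbabilityMap, build_model
from cactuscover.mosaic import (MosaicPrediction, binarize, overlay,
                                quantization_floor_mask, segment_orthomosaic,
                                upscale_mask)
from conftest import random_image, random_mask


class TestBinarize:
    def test_tie_goes_to_foreground(self):
        pm = ProbabilityMap(np.full((4, 4), 0.5, np.float32), "m")
        assert (binarize(pm, 0.5).values == 1).all()

    def test_high_threshold_empties_mask(self, rng):
        pm = ProbabilityMap(rng.uniform(0, 0.9, (6, 6)), "m")
        assert binarize(pm, 0.999).values.sum() == 0

    def test_foreground_monotone_in_threshold(self, rng):
        pm = ProbabilityMap(rng.random((32, 32)), "m")
        counts = [int(binarize(pm, t).values.sum())
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(InvalidParameterError):
            binarize(ProbabilityMap(np.zeros((2, 2)), "m"), bad)


class TestUpscaleMask:
    def test_all_ones_stays_all_ones_at_mosaic_scale(self):
        up = upscale_mask(BinaryMask(np.ones((160, 160), np.uint8)),
                          1125, 2000)
        assert up.shape == (1125, 2000)
        assert (up.values == 1).all()

    def test_integer_factor_round_trip(self, rng):
        m = random_mask(rng, 20, 30)
        up = upscale_mask(m, 40, 60)
        down = up.values[::2, ::2]
        assert np.array_equal(down, m.values)
        assert set(np.unique(up.values)) <= {0, 1}

    def test_shrinking_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            upscale_mask(random_mask(rng, 10, 10), 5, 20)


class _ConstantModel:
    """Test double satisfying the SegModel inference protocol."""

    def __init__(self, value: float, input_size: int = 16):
        self.spec = ModelSpec("unet", input_size=input_size, base_filters=1,
                              depth=1)
        self.id = f"const-{value}"
        self.value = value

    def predict_batch(self, batch):
        n, h, w, _ = batch.shape
        return np.full((n, h, w), self.value, np.float32)


class TestSegmentOrthomosaic:
    def _image(self, rng, h=40, w=60):
        return random_image(rng, h, w, id="mosaic")

    def test_constant_one_model_fills_everything(self, rng):
        img = self._image(rng)
        pred = segment_orthomosaic(_ConstantModel(1.0), img)
        assert isinstance(pred, MosaicPrediction)
        assert pred.full_mask.shape == img.shape
        assert pred.full_mask.foreground_count() == 40 * 60

    def test_full_mask_count_equals_tile_count_sum(self):
        params = SceneParams(width_px=240, height_px=180, n_rows=2,
                             plants_per_row=3, paddle_axis_px=(5, 14), seed=4)
        image, _, _ = generate_scene(params)
        model = build_model(ModelSpec("unet", input_size=16, base_filters=2,
                                      depth=2))
        pred = segment_orthomosaic(model, image)
        assert pred.full_mask.shape == image.shape
        tile_sum = sum(int(m.values.sum()) for m in pred.tile_masks)
        assert pred.full_mask.foreground_count() == tile_sum

    def test_repeated_calls_identical(self, rng):
        img = self._image(rng)
        model = build_model(ModelSpec("unet", input_size=16, base_filters=2,
                                      depth=2))
        a = segment_orthomosaic(model, img)
        b = segment_orthomosaic(model, img)
        assert np.array_equal(a.full_mask.values, b.full_mask.values)

    def test_recursive_split_keeps_exact_dimensions(self, rng):
        # force two split levels with a small tile cap
        img = self._image(rng, 130, 202)
        pred = segment_orthomosaic(_ConstantModel(1.0), img, max_tile_px=64)
        assert pred.full_mask.shape == (130, 202)
        assert pred.full_mask.foreground_count() == 130 * 202
        assert len(pred.tile_probability_maps) == 16


class TestOverlay:
    def test_empty_mask_leaves_image_untouched(self, rng):
        img = random_image(rng, 12, 12)
        mask = BinaryMask(np.zeros((12, 12), np.uint8))
        assert np.array_equal(overlay(img, mask), img.pixels)

    def test_full_mask_full_blend_is_pure_color(self, rng):
        img = random_image(rng, 8, 8)
        mask = BinaryMask(np.ones((8, 8), np.uint8))
        out = overlay(img, mask, color=(0, 0, 255), blend=1.0)
        assert (out == np.array([0, 0, 255], np.uint8)).all()

    def test_background_pixels_bit_identical(self, rng):
        img = random_image(rng, 16, 16)
        mask = random_mask(rng, 16, 16, p=0.4)
        out = overlay(img, mask)
        bg = mask.values == 0
        assert np.array_equal(out[bg], img.pixels[bg])

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(AlignmentError):
            overlay(random_image(rng, 8, 8), random_mask(rng, 8, 9))


class TestQuantizationFloor:
    def test_perfect_model_recovers_area_within_five_percent(self):
        """The tiling/resize round-trip alone must not distort cover by
        more than 5% — the accuracy floor of the whole pipeline."""
        for seed in range(5):
            params = SceneParams(width_px=800, height_px=448, n_rows=4,
                                 plants_per_row=8, paddle_axis_px=(8, 24),
                                 seed=seed)
            _, mask, scene = generate_scene(params)
            floor = quantization_floor_mask(mask, model_size=160)
            est = floor.foreground_count() * params.pixel_area_m2
            assert est == pytest.approx(scene.true_area_m2, rel=0.05)

    def test_constant_masks_unchanged(self):
        ones = BinaryMask(np.ones((64, 96), np.uint8))
        assert (quantization_floor_mask(ones, 16).values == 1).all()
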