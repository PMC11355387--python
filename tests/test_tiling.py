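"""Quadrant tiling: exact split/reassembly, binary-preserving resize,
augmentation cardinality, and leakage-free dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cactuscover import AlignmentError, BinaryMask, ConfigurationError, \
    InvalidParameterError, OrthoImage, ReassemblyError
from cactuscover.tiling import (augment_pair, build_dataset,
                                reassemble_quadrants, resize_pair,
                                split_into_quadrants, tile_scene)
from conftest import random_image, random_mask


def make_pair(rng, h, w, id="img"):
    return random_image(rng, h, w, id=id), random_mask(rng, h, w)


class TestSplitReassemble:
    def test_even_4000x2250_gives_2000x1125_quadrants(self):
        img = OrthoImage(np.zeros((2250, 4000, 3), np.uint8), 1.0)
        mask = BinaryMask(np.zeros((2250, 4000), np.uint8))
        tiles = split_into_quadrants(img, mask)
        assert [(t.native_height, t.native_width) for t in tiles] == \
            [(1125, 2000)] * 4

    def test_odd_5x5_top_left_take_the_extra_pixel(self, rng):
        img, mask = make_pair(rng, 5, 5)
        tiles = split_into_quadrants(img, mask)
        assert [(t.native_height, t.native_width) for t in tiles] == \
            [(3, 3), (3, 2), (2, 3), (2, 2)]
        assert [(t.row_offset, t.col_offset) for t in tiles] == \
            [(0, 0), (0, 3), (3, 0), (3, 3)]

    def test_foreground_counts_are_conserved(self, rng):
        for _ in range(10):
            img, mask = make_pair(rng, 36, 64)
            tiles = split_into_quadrants(img, mask)
            assert sum(int(t.native_mask.sum()) for t in tiles) == \
                int(mask.values.sum())

    def test_round_trip_bit_exact_and_order_independent(self, rng):
        img, mask = make_pair(rng, 37, 23)
        tiles = split_into_quadrants(img, mask)
        for order in ([0, 1, 2, 3], [3, 1, 0, 2]):
            rimg, rmask = reassemble_quadrants([tiles[i] for i in order])
            assert np.array_equal(rimg, img.pixels)
            assert np.array_equal(rmask, mask.values)

    def test_shape_mismatch_raises_alignment_error(self, rng):
        img = random_image(rng, 10, 10)
        with pytest.raises(AlignmentError):
            split_into_quadrants(img, random_mask(rng, 10, 11))

    def test_mixed_parents_raise(self, rng):
        a = split_into_quadrants(*make_pair(rng, 8, 8, id="a"))
        b = split_into_quadrants(*make_pair(rng, 8, 8, id="b"))
        with pytest.raises(ReassemblyError):
            reassemble_quadrants(a[:3] + b[3:])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(h=st.integers(2, 40), w=st.integers(2, 40), seed=st.integers(0, 99))
    def test_property_round_trip_any_shape(self, h, w, seed):
        r = np.random.default_rng(seed)
        img, mask = make_pair(r, h, w)
        tiles = split_into_quadrants(img, mask)
        rimg, rmask = reassemble_quadrants(tiles)
        assert np.array_equal(rimg, img.pixels)
        assert np.array_equal(rmask, mask.values)
        assert sum(int(t.native_mask.sum()) for t in tiles) == \
            int(mask.values.sum())


class TestResizePair:
    def test_2000x1125_tile_resizes_to_160(self, rng):
        img, mask = make_pair(rng, 2250, 4000)
        tile = split_into_quadrants(img, mask)[0]
        out = resize_pair(tile, 160)
        assert out.model_image.shape == (160, 160, 3)
        assert out.model_mask.shape == (160, 160)

    def test_constant_mask_stays_constant(self, rng):
        img = random_image(rng, 33, 57)
        mask = BinaryMask(np.ones((33, 57), np.uint8))
        tile = split_into_quadrants(img, mask)[0]
        out = resize_pair(tile, 160)
        assert (out.model_mask == 1).all()

    def test_mask_values_stay_binary(self, rng):
        img, mask = make_pair(rng, 47, 31)
        for tile in split_into_quadrants(img, mask):
            out = resize_pair(tile, 16)
            assert set(np.unique(out.model_mask)) <= {0, 1}

    def test_tiny_model_size_rejected(self, rng):
        tile = split_into_quadrants(*make_pair(rng, 20, 20))[0]
        with pytest.raises(InvalidParameterError):
            resize_pair(tile, 4)


class TestAugmentPair:
    def _model_tile(self, rng, size=16):
        img, mask = make_pair(rng, size * 2, size * 2)
        return resize_pair(split_into_quadrants(img, mask)[0], size)

    def test_exactly_four_variants_with_equal_foreground(self, rng):
        tile = self._model_tile(rng)
        variants = augment_pair(tile)
        assert len(variants) == 4
        assert [v.augmentation for v in variants] == \
            ["identity", "hflip", "rot90", "rot180"]
        counts = {int(v.model_mask.sum()) for v in variants}
        assert len(counts) == 1

    def test_rot180_is_an_involution(self, rng):
        tile = self._model_tile(rng)
        once = augment_pair(tile)[3]
        twice = augment_pair(once)[3]
        assert np.array_equal(twice.model_image, tile.model_image)
        assert np.array_equal(twice.model_mask, tile.model_mask)

    def test_image_and_mask_transformed_identically(self, rng):
        tile = self._model_tile(rng)
        for v in augment_pair(tile):
            if v.augmentation == "hflip":
                assert np.array_equal(v.model_mask, tile.model_mask[:, ::-1])
                assert np.array_equal(v.model_image, tile.model_image[:, ::-1])

    def test_non_square_model_raster_rejected(self, rng):
        tile = self._model_tile(rng)
        bad = type(tile)(**{**tile.__dict__,
                            "model_mask": tile.model_mask[:8]})
        with pytest.raises(InvalidParameterError):
            augment_pair(bad)


class TestBuildDataset:
    def _scenes(self, rng, n, h=40, w=64):
        return [make_pair(rng, h, w, id=f"s{i}") for i in range(n)]

    def test_accounting_example_4_scenes(self, rng):
        split = build_dataset(self._scenes(rng, 4), 0.5, 0.25, seed=0,
                              model_size=16)
        acc = split.accounting
        assert (acc["train_sources"], acc["validation_sources"],
                acc["test_sources"]) == (2, 1, 1)
        assert acc["train_tiles"] == 8
        assert acc["augmented"] == 32
        assert len(split.train_tiles) == 32

    def test_augmentation_cardinality_always_4x(self, rng):
        for n, tf, vf in [(5, 0.4, 0.2), (8, 0.5, 0.25)]:
            split = build_dataset(self._scenes(rng, n), tf, vf, seed=1,
                                  model_size=16)
            assert split.accounting["augmented"] == \
                4 * split.accounting["train_tiles"]

    def test_no_source_leaks_between_splits(self, rng):
        split = build_dataset(self._scenes(rng, 9), 0.5, 0.25, seed=2,
                              model_size=16)
        groups = [set(split.train_sources), set(split.validation_sources),
                  set(split.test_sources)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not groups[i] & groups[j]
        for t in split.train_tiles:
            assert t.parent_id in groups[0]

    def test_same_seed_reproduces_membership(self, rng):
        scenes = self._scenes(rng, 6)
        a = build_dataset(scenes, 0.5, 0.2, seed=3, model_size=16)
        b = build_dataset(scenes, 0.5, 0.2, seed=3, model_size=16)
        assert a.train_sources == b.train_sources
        assert a.validation_sources == b.validation_sources
        assert a.test_sources == b.test_sources

    def test_too_few_scenes_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            build_dataset(self._scenes(rng, 2), 0.5, 0.4, seed=0,
                          model_size=16)

    def test_masks_binary_everywhere(self, rng):
        split = build_dataset(self._scenes(rng, 4), 0.5, 0.25, seed=0,
                              model_size=16)
        for tiles in (split.train_tiles, split.validation_tiles,
                      split.test_tiles):
            for t in tiles:
                assert set(np.unique(t.model_mask)) <= {0, 1}


def test_tile_scene_keeps_offsets_for_native_drop(rng):
    img, mask = make_pair(rng, 30, 44)
    tiles = tile_scene(img, mask, model_size=16)
    assert all(t.native_image is None for t in tiles)
    assert [(t.row_offset, t.col_offset) for t in tiles] == \
        [(0, 0), (0, 22), (15, 0), (15, 22)]
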