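import numpy as np
import pytest

from cactuscover import BinaryMask, OrthoImage, SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 400x225 rendered scene with exact truth (session-cached)."""
    params = SceneParams(width_px=400, height_px=225, n_rows=3,
                         plants_per_row=4, paddle_axis_px=(6.0, 18.0), seed=7)
    image, mask, scene = generate_scene(params)
    return params, image, mask, scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, h, w, p=0.3) -> BinaryMask:
    return BinaryMask((rng.random((h, w)) < p).astype(np.uint8))


def random_image(rng, h, w, pixel_area=1.0, id="img") -> OrthoImage:
    return OrthoImage(rng.integers(0, 256, (h, w, 3), dtype=np.uint8),
                      pixel_area, id=id)
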