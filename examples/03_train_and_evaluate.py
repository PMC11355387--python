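"""Train the three segmentation architectures on a tiny synthetic dataset.

Uses small tiles (64 px) and few scenes so the run finishes in about a
minute per architecture on a laptop CPU; prints the per-epoch validation
IoU and the held-out tile IoU for each network.
"""

from cactuscover import SceneParams, generate_scenes
from cactuscover.models import ModelSpec, build_model
from cactuscover.tiling import build_dataset
from cactuscover.training import TrainConfig, train, _evaluate, _tiles_to_arrays

base = SceneParams(width_px=320, height_px=320, n_rows=3, plants_per_row=5,
                   paddle_axis_px=(6, 18))
scenes = generate_scenes(base, 10, seed=11)
split = build_dataset(scenes, 0.5, 0.2, seed=0, model_size=64)
x_test, y_test = _tiles_to_arrays(split.test_tiles)

for arch in ("unet", "deeplabv3plus", "unet_xception"):
    model = build_model(ModelSpec(arch, input_size=64, base_filters=8, depth=3))
    model, hist = train(model, split, TrainConfig(
        epochs=10, batch_size=8, learning_rate=2e-3, seed=1))
    _, test_iou = _evaluate(model, x_test, y_test, 8, 0.5)
    print(f"{arch:>15}: val IoU per epoch "
          f"{[round(v, 2) for v in hist.val_iou]}")
    print(f"{'':>15}  best epoch {hist.best_epoch}, held-out tile IoU "
          f"{test_iou:.3f}")
# IoU is intersection-over-union between the thresholded prediction and
# the ground-truth mask; 1.0 is perfect overlap, and values above ~0.5
# mean the network has genuinely learned the canopy/soil boundary.
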