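# Methods

## The problem

Quantifying canopy cover of row-planted *Opuntia* (prickly pear) fields
from drone orthophotos requires per-pixel vegetation/background
segmentation of images far larger than any practical CNN input.  The
package implements the complete measurement pipeline — tile, downscale,
predict, binarise, upscale, reassemble, count — together with a synthetic
scene generator that provides exact ground truth, so the whole chain can be
validated quantitatively without field imagery or manual annotation.

## Synthetic cactus-field scenes

`cactuscover.field` renders nadir orthophotos of a row crop:

* **Layout.** `n_rows` horizontal furrow bands; `plants_per_row` plants per
  band with Gaussian jitter (12% of the column gap laterally, 10% of the
  row gap vertically), matching the central-furrow planting pattern of
  cactus-pear cultivation.
* **Canopy.** Each plant is 1–8 overlapping rotated ellipses ("paddles"),
  the simplest shape family with cladode-like silhouettes.  Semi-major
  axes are drawn uniformly from `paddle_axis_px`; the aspect ratio is
  uniform in [0.40, 0.65].
* **Soil.** Brown base colour modulated by low-frequency value noise
  (bilinear-upscaled coarse Gaussian grid) plus per-pixel speckle and
  channel mottle, so soil is not separable by a single grey threshold.
* **Photometric effects.** Per-paddle cast shadows in a fixed sun
  direction, low-frequency canopy hue jitter, per-pixel leaf texture, and
  a mild illumination ramp in a seeded random direction.
* **Capture styles.** Three styles emulate nadir (90°) and oblique
  (45°/135°) acquisition.  Oblique views are horizontal shears (±0.08,
  unit determinant, about the frame centre) of the rendered nadir scene
  rather than 3-D re-renders: the pipeline consumes orthophotos, so only
  the mild geometric/photometric perturbation matters, not perspective
  itself.  Shear uses linear interpolation for images and
  nearest-neighbour for masks (masks stay binary); it conserves
  foreground count to within a few percent (only frame-edge clipping and
  rasterisation change it).

Ground truth is exact by construction: `true_foreground_px` is the
foreground count of the rendered mask and
`true_area_m2 = true_foreground_px x pixel_area_m2` exactly.

**Ground scale.** The default pixel area is 54.1950 / 128 959 m^2/px
(≈ 4.2025 x 10^-4, i.e. a ~2.05 cm ground sampling distance), anchoring
synthetic areas to the reference survey scale of a ~54 m^2 plot.  Because
the survey never states its GSD directly, pixel area is a free parameter
everywhere.

**What the generator does not emulate:** photogrammetric stitching
artefacts, perspective distortion, weeds and non-crop vegetation,
multispectral bands, motion blur, and radiometric calibration.  Passing
tests therefore demonstrate that the *pipeline machinery* is correct and
that the architectures can learn this class of segmentation problem; they
do not certify accuracy on real field imagery.

## Dataset construction

Full scenes (default 4000 x 2250 px) are split into four quadrants
(top-left, top-right, bottom-left, bottom-right; odd dimensions give the
extra pixel to top/left), each resized to 160 x 160 — bilinear for images,
nearest-neighbour for masks so the value set {0,1} survives exactly.
Training tiles are expanded four-fold with {identity, horizontal flip,
90° rotation, 180° rotation}; "flip" direction is horizontal, the common
default.  294 training sources therefore yield 294 x 4 x 4 = 4704 items.
Splitting is always at the source-image level so no parent raster leaks
between train/validation/test; the validation share (default 15%) is
carved out because best-epoch checkpointing needs one, even though the
original protocol never sizes it.  The three capture styles are pooled
for training and retained as tags for stratified reporting.

## Architectures

All three networks map `input_size x input_size x 3` inputs in [0,1] to a
same-size probability map through a single-channel sigmoid head ('same'
padding throughout; the binary task needs no two-channel softmax).  They
are built on `cactuscover.nn`, a small reverse-mode autodiff engine over
numpy (tap-wise convolutions routed through BLAS; verified against
central finite differences in the test suite).  Width and depth are
exposed (`base_filters`, `depth`) so the same code runs desk-scale and
larger.

* **UNet** — `depth` encoder stages of two 3x3 conv + ReLU with 2x2
  max-pooling, a bridge, and a symmetric decoder of 2x2 transposed
  convolutions with skip concatenations.
* **DeepLabV3+** — a small strided-conv backbone (stride 2 per stage,
  channels doubling; the stride-4 stage provides the low-level skip), an
  atrous pyramid with one 3x3 branch per dilation rate (default 1, 6, 12,
  18) plus an image-level pooling branch, a 1x1 merge, and a decoder that
  upsamples, concatenates the projected low-level feature, refines with
  two 3x3 convs and restores full resolution.  The backbone is
  self-built rather than pretrained: no external weight dependency, full
  seed reproducibility.
* **UNet Style Xception** — UNet topology whose blocks use
  depthwise-separable 3x3 convolutions (per-channel spatial conv + 1x1
  pointwise) with 1x1 residual shortcut projections.  Residual sums are
  scaled by 1/sqrt(2) to keep activation variance flat across blocks;
  without this the randomly-initialised network saturates its sigmoid
  head and trains slowly.  Separable blocks have strictly fewer
  parameters than standard blocks at equal filter counts.

Initialisation is He-normal from the spec seed; biases start at zero
(hence a freshly built model maps a zero image to a constant 0.5 map).

## Training

Pixel-wise binary cross-entropy with Adam.  The update uses the fused
logits form of the loss (identical value to the probability-space
definition with clipping at 1e-7, but saturation-free gradients); the
reported loss is the same quantity.  After each epoch the model is scored
on validation tiles by pooled IoU at threshold 0.5; the returned
parameters are those of the best-validation-IoU epoch, ties broken by
lower validation loss.  Defaults: 50 epochs, batch 16, learning rate
1e-3, all configurable.  Runs are bit-deterministic on CPU for fixed
seeds (data order from the training seed, weights from the model seed).

## Mosaic inference

Per quadrant: bilinear downscale to model resolution, predict, binarise
(ties at the threshold go to foreground), nearest-neighbour upscale of
the *binary* mask back to native size, then offset-governed reassembly.
Binarising before upscaling mirrors the mask-resizing order of the field
protocol and keeps every stored mask binary.  Quadrants larger than a
configurable cap (default 2000 px) are split recursively, so arbitrarily
large mosaics reduce to model-size tiles while the output mask always has
exactly the input dimensions.  Foreground is alpha-blended toward blue
(default 0.6) for the overlay product; background pixels are untouched.

The *quantisation floor* utility pushes the ground-truth mask itself
through the same split/resize round-trip: the residual area error (below
5% at desk scale) is the accuracy ceiling the resolution pipeline imposes
on any model.

## Quantification and reporting

Vegetation area is pixel count x pixel area.  IoU follows the standard
intersection-over-union definition with the empty-empty case defined as
1.0 (agreement on absence, avoiding 0/0).  RMSE is reported over
foreground pixel counts; because the observation unit of the original
survey's RMSE is not defined, the package states its own: per-test-tile
counts at model resolution for tile-level evaluation, per-quadrant counts
at native resolution for mosaic-level reports.  Area tables print one row
per model (count, m^2, IoU, RMSE) plus a reference row (IoU 1, RMSE 0),
with 4-decimal formatting.

## Desk-scale study conditions

The packaged experiment (`cactuscover.pipeline.default_config`, also used
by `scripts/acceptance.py`) is sized for a single CPU: 40 scenes at
800 x 448 px native resolution, 65/15/20 train/validation/test split at
source level, 160 x 160 model tiles, `base_filters` 16, `depth` 3, 2
epochs of Adam at learning rate 2e-3, batch 8, threshold 0.5.  Under
these conditions all three architectures reach held-out tile IoU well
above 0.5 (UNet ≈ 0.95+, separable UNet ≈ 0.9, DeepLabV3+ ≈ 0.8), with
the training loss descending across epochs.  These synthetic-scene scores
are not comparable to published field results, which depend on real
imagery that is not distributed.

## Numerical and engineering choices

* float32 rendering and training throughout; float64 only in metric
  reporting.
* Binarisation threshold 0.5 with ties to foreground.
* Max-pool gradients split evenly among tied maxima.
* Odd-dimension tiling: top/left quadrants take the extra pixel;
  offsets are 0-based, row-major, half-open.
* glibc's allocator is tuned at import (`mallopt`: no mmap for large
  blocks, no trim) because the pipeline cycles many ~100 MB raster
  buffers; keeping them in the heap avoids paying soft-page-fault costs
  on every fresh allocation.  Resident memory then stays near its
  high-water mark, acceptable for these working sets.
* `build_dataset` streams scenes and keeps only model-resolution tiles,
  so hundreds of full-size parents fit in memory.

## Known limitations

* The autodiff engine is CPU-only and unoptimised relative to real deep
  learning frameworks; large-scale training is out of scope.
* No batch normalisation; very deep configurations would need it.
* The oblique emulation is a shear, not a perspective re-projection.
* Plant counting / instance segmentation is not implemented.
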