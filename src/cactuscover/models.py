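"""The three segmentation architectures behind one interface.

All three map an ``input_size x input_size`` RGB image (intensities in
[0, 1]) to a per-pixel vegetation probability map of the same spatial size:

* ``unet`` — classic encoder/decoder with skip concatenations: repeated
  blocks of two 3x3 convolutions + ReLU, 2x2 max-pooling on the way down,
  2x2 up-convolutions and skip concatenation on the way up, 1x1 sigmoid
  head.
* ``deeplabv3plus`` — small strided-convolution backbone, an atrous
  spatial pyramid (one 3x3 branch per dilation rate plus an image-level
  pooling branch), and a decoder that upsamples, concatenates a low-level
  skip feature, refines with 3x3 convolutions and restores full
  resolution.
* ``unet_xception`` — UNet topology whose blocks use depthwise-separable
  3x3 convolutions with 1x1 residual shortcut projections, trading a large
  parameter reduction for little accuracy.

Everything is built on the package's numpy autodiff engine; 'same' padding
keeps output size equal to input size, and the binary task uses a
single-channel sigmoid head.  Width (``base_filters``) and depth are
exposed so the networks scale from desk-size experiments upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import InvalidParameterError, ShapeError
from .nn import ops
from .nn.tensor import Tensor, no_grad

ARCHITECTURES = ("unet", "deeplabv3plus", "unet_xception")


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    input_size: int = 160
    base_filters: int = 32
    depth: int = 4
    atrous_rates: tuple[int, ...] = (1, 6, 12, 18)
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise InvalidParameterError(
                f"architecture must be one of {ARCHITECTURES}")
        if self.base_filters < 1:
            raise InvalidParameterError("base_filters must be >= 1")
        if self.depth < 1:
            raise InvalidParameterError("depth must be >= 1")
        if self.input_size % (2 ** self.depth):
            raise InvalidParameterError(
                f"input_size {self.input_size} not divisible by "
                f"2^depth = {2 ** self.depth}")
        if self.architecture == "deeplabv3plus":
            if self.depth < 3:
                raise InvalidParameterError(
                    "deeplabv3plus needs depth >= 3 (low-level skip at "
                    "stride 4, high-level features deeper)")
            if any(r < 1 for r in self.atrous_rates) or not self.atrous_rates:
                raise InvalidParameterError(
                    "atrous_rates must be a non-empty list of positive ints")


@dataclass
class ProbabilityMap:
    """Pre-threshold model output: per-pixel foreground probability."""

    values: np.ndarray           # (H, W) float32 in [0, 1]
    model_id: str


class _ConvBlock(nn.Module):
    """Two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)

    def __call__(self, x):
        return ops.relu(self.c2(ops.relu(self.c1(x))))


class _UNet(nn.Module):
    def __init__(self, spec: ModelSpec, rng):
        F, D = spec.base_filters, spec.depth
        widths = [F * 2 ** i for i in range(D)]
        self.enc = []
        cin = 3
        for wdt in widths:
            self.enc.append(_ConvBlock(cin, wdt, rng))
            cin = wdt
        self.bridge = _ConvBlock(widths[-1], F * 2 ** D, rng)
        self.ups = []
        self.dec = []
        for wdt in reversed(widths):
            self.ups.append(nn.ConvTranspose2x2(wdt * 2, wdt, rng))
            self.dec.append(_ConvBlock(wdt * 2, wdt, rng))
        self.head = nn.Conv2d(widths[0], 1, 1, rng)

    def __call__(self, x):
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = ops.maxpool2x2(x)
        x = self.bridge(x)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x)
            x = blk(ops.concat_channels([x, skip]))
        return self.head(x)


class _XceptionEncBlock(nn.Module):
    """ReLU-sepconv-ReLU-sepconv, max-pooled, with a strided 1x1 shortcut."""

    def __init__(self, cin, cout, rng):
        self.s1 = nn.SeparableConv2d(cin, cout, rng)
        self.s2 = nn.SeparableConv2d(cout, cout, rng)
        self.proj = nn.Conv2d(cin, cout, 1, rng, stride=2, padding=0)

    def __call__(self, x):
        y = self.s1(ops.relu(x))
        skip = self.s2(ops.relu(y))          # pre-pool feature for UNet concat
        out = ops.scale(ops.add(ops.maxpool2x2(skip), self.proj(x)),
                        2 ** -0.5)           # keep variance flat across blocks
        return out, skip


class _XceptionDecBlock(nn.Module):
    """Upsample, concat skip, two sepconvs, with a 1x1 shortcut."""

    def __init__(self, cin_cat, cout, rng):
        self.s1 = nn.SeparableConv2d(cin_cat, cout, rng)
        self.s2 = nn.SeparableConv2d(cout, cout, rng)
        self.proj = nn.Conv2d(cin_cat, cout, 1, rng)

    def __call__(self, x_cat):
        y = self.s1(ops.relu(x_cat))
        y = self.s2(ops.relu(y))
        return ops.scale(ops.add(y, self.proj(x_cat)), 2 ** -0.5)


class _UNetXception(nn.Module):
    def __init__(self, spec: ModelSpec, rng):
        F, D = spec.base_filters, spec.depth
        widths = [F * 2 ** i for i in range(D)]
        self.stem = nn.Conv2d(3, F, 3, rng)
        self.enc = []
        cin = F
        for wdt in widths:
            self.enc.append(_XceptionEncBlock(cin, wdt, rng))
            cin = wdt
        self.bridge = _XceptionDecBlock(widths[-1], F * 2 ** D, rng)
        self.dec = []
        cin = F * 2 ** D
        for wdt in reversed(widths):
            self.dec.append(_XceptionDecBlock(cin + wdt, wdt, rng))
            cin = wdt
        self.head = nn.Conv2d(widths[0], 1, 1, rng)

    def __call__(self, x):
        x = ops.relu(self.stem(x))
        skips = []
        for blk in self.enc:
            x, skip = blk(x)
            skips.append(skip)
        x = self.bridge(x)
        for blk, skip in zip(self.dec, reversed(skips)):
            x = ops.upsample_nearest(x, 2)
            x = blk(ops.concat_channels([x, skip]))
        return self.head(x)


class _DeepLabV3Plus(nn.Module):
    def __init__(self, spec: ModelSpec, rng):
        F, D = spec.base_filters, spec.depth
        self.rates = tuple(spec.atrous_rates)
        # strided backbone: stride 2 per stage, channels double each stage
        self.backbone = []
        cin = 3
        for i in range(D):
            cout = F * 2 ** i
            self.backbone.append(nn.Conv2d(cin, cout, 3, rng, stride=2))
            cin = cout
        C = F * 4                              # pyramid projection width
        self.aspp = [nn.Conv2d(cin, C, 3, rng, dilation=r) for r in self.rates]
        self.pool_proj = nn.Conv2d(cin, C, 1, rng)
        self.merge = nn.Conv2d(C * (len(self.rates) + 1), C, 1, rng)
        self.low_proj = nn.Conv2d(F * 2, F, 1, rng)
        self.refine1 = nn.Conv2d(C + F, C, 3, rng)
        self.refine2 = nn.Conv2d(C, C, 3, rng)
        self.head = nn.Conv2d(C, 1, 1, rng)
        self.up1 = 2 ** D // 4                 # high-level -> stride 4
        self.low_stage = 1                     # output of 2nd backbone conv

    def __call__(self, x):
        low = None
        for i, conv in enumerate(self.backbone):
            x = ops.relu(conv(x))
            if i == self.low_stage:
                low = x
        h, w = x.data.shape[2], x.data.shape[3]
        branches = [ops.relu(a(x)) for a in self.aspp]
        pooled = ops.relu(self.pool_proj(ops.global_avg_pool(x)))
        branches.append(ops.broadcast_hw(pooled, h, w))
        y = ops.relu(self.merge(ops.concat_channels(branches)))
        if self.up1 > 1:
            y = ops.upsample_nearest(y, self.up1)
        y = ops.concat_channels([y, ops.relu(self.low_proj(low))])
        y = ops.relu(self.refine1(y))
        y = ops.relu(self.refine2(y))
        y = ops.upsample_nearest(y, 4)
        return self.head(y)


_BUILDERS = {"unet": _UNet, "deeplabv3plus": _DeepLabV3Plus,
             "unet_xception": _UNetXception}


class SegModel:
    """A parameterised image -> per-pixel-probability function."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.net = _BUILDERS[spec.architecture](spec, rng)
        self.id = f"{spec.architecture}-s{spec.seed}"

    # -- training-facing API -------------------------------------------------
    def forward_logits(self, batch: np.ndarray) -> Tensor:
        """Logits for a float32 NHWC batch scaled to [0, 1]."""
        x = Tensor(np.ascontiguousarray(batch.transpose(0, 3, 1, 2)))
        return self.net(x)

    def parameters(self):
        return self.net.parameters()

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def state(self):
        return self.net.state()

    def load_state(self, state):
        self.net.load_state(state)

    # -- inference-facing API ------------------------------------------------
    def predict_batch(self, batch: np.ndarray) -> np.ndarray:
        """Probabilities for an NHWC float batch; no autodiff graph."""
        with no_grad():
            logits = self.forward_logits(batch.astype(np.float32, copy=False))
            return ops.sigmoid(logits).data[:, 0]


def build_unet(spec: ModelSpec) -> SegModel:
    if spec.architecture != "unet":
        raise InvalidParameterError("spec.architecture must be 'unet'")
    return SegModel(spec)


def build_deeplabv3plus(spec: ModelSpec) -> SegModel:
    if spec.architecture != "deeplabv3plus":
        raise InvalidParameterError("spec.architecture must be 'deeplabv3plus'")
    return SegModel(spec)


def build_unet_xception(spec: ModelSpec) -> SegModel:
    if spec.architecture != "unet_xception":
        raise InvalidParameterError("spec.architecture must be 'unet_xception'")
    return SegModel(spec)


def build_model(spec: ModelSpec) -> SegModel:
    """Dispatch on ``spec.architecture``."""
    return SegModel(spec)


def predict(model: SegModel, image: np.ndarray) -> ProbabilityMap:
    """Probability map for one ``input_size``-squared RGB image in [0, 1].

    No silent resizing: a wrong spatial size raises ShapeError (resizing is
    the tiling stage's job).
    """
    image = np.asarray(image)
    s = model.spec.input_size
    if image.shape != (s, s, 3):
        raise ShapeError(
            f"expected {(s, s, 3)} input, got {image.shape}")
    if image.dtype.kind not in "fd" or image.min() < 0 or image.max() > 1.0 + 1e-6:
        raise InvalidParameterError(
            "predict expects float intensities pre-scaled to [0, 1]")
    probs = model.predict_batch(image[None].astype(np.float32))
    return ProbabilityMap(values=probs[0], model_id=model.id)
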