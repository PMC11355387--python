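"""Differentiable operations used by the segmentation networks.

All spatial tensors are NCHW.  Convolutions are computed tap-by-tap: a
``kh x kw`` kernel becomes ``kh*kw`` batched matrix products against shifted
views of the (padded) input, which keeps dilation and stride support trivial
and routes the heavy lifting through BLAS.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, make_op


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _conv_geometry(H, W, kh, kw, stride, dilation, padding):
    if padding == "same":
        if stride != 1 and (H % stride or W % stride):
            raise ValueError("'same' padding with stride needs divisible input size")
        ph = dilation * (kh - 1) // 2
        pw = dilation * (kw - 1) // 2
    else:
        ph = pw = int(padding)
    Ho = (H + 2 * ph - dilation * (kh - 1) - 1) // stride + 1
    Wo = (W + 2 * pw - dilation * (kw - 1) - 1) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("kernel larger than padded input")
    return ph, pw, Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, dilation: int = 1, padding="same") -> Tensor:
    """2-D convolution (cross-correlation). ``w``: (O, C, kh, kw)."""
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    s, d = stride, dilation
    ph, pw, Ho, Wo = _conv_geometry(H, W, kh, kw, s, d, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    out = np.zeros((N, O, Ho * Wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * d: i * d + s * Ho: s, j * d: j * d + s * Wo: s]
            out += np.matmul(w.data[:, :, i, j], xs.reshape(N, C, Ho * Wo))
    out = out.reshape(N, O, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1)

    def backward(dy):
        dyf = dy.reshape(N, O, Ho * Wo)
        need_x = x.requires_grad or x._parents
        dxp = np.zeros_like(xp) if need_x else None
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None),
                      slice(i * d, i * d + s * Ho, s),
                      slice(j * d, j * d + s * Wo, s))
                if w.requires_grad:
                    xs = xp[sl].reshape(N, C, Ho * Wo)
                    dw_tap = np.matmul(dyf, xs.transpose(0, 2, 1)).sum(axis=0)
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, i, j] += dw_tap
                if need_x:
                    dxp[sl] += np.matmul(w.data[:, :, i, j].T, dyf).reshape(N, C, Ho, Wo)
        if need_x:
            dx = dxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else dxp
            x.accumulate_grad(dx)
        if b is not None and b.requires_grad:
            b.accumulate_grad(dy.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return make_op(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                     dilation: int = 1) -> Tensor:
    """Per-channel spatial convolution. ``w``: (C, kh, kw)."""
    N, C, H, W = x.data.shape
    Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    d = dilation
    ph, pw, Ho, Wo = _conv_geometry(H, W, kh, kw, 1, d, "same")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((N, C, Ho, Wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * d: i * d + Ho, j * d: j * d + Wo]
            out += xs * w.data[:, i, j][None, :, None, None]
    if b is not None:
        out += b.data.reshape(1, C, 1, 1)

    def backward(dy):
        need_x = x.requires_grad or x._parents
        dxp = np.zeros_like(xp) if need_x else None
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None),
                      slice(i * d, i * d + Ho), slice(j * d, j * d + Wo))
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, i, j] += (dy * xp[sl]).sum(axis=(0, 2, 3))
                if need_x:
                    dxp[sl] += dy * w.data[:, i, j][None, :, None, None]
        if need_x:
            x.accumulate_grad(dxp[:, :, ph:ph + H, pw:pw + W])
        if b is not None and b.requires_grad:
            b.accumulate_grad(dy.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return make_op(out, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 stride-2 transposed convolution (the UNet 'up-convolution').

    ``w``: (C_in, C_out, 2, 2); output is (N, C_out, 2H, 2W).
    """
    N, C, H, W = x.data.shape
    Cw, O = w.data.shape[:2]
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    xf = x.data.transpose(0, 2, 3, 1).reshape(N * H * W, C)
    yf = xf @ w.data.reshape(C, O * 4)
    out = (yf.reshape(N, H, W, O, 2, 2)
             .transpose(0, 3, 1, 4, 2, 5)
             .reshape(N, O, 2 * H, 2 * W))
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def backward(dy):
        dyf = (dy.reshape(N, O, H, 2, W, 2)
                 .transpose(0, 2, 4, 1, 3, 5)
                 .reshape(N * H * W, O * 4))
        if w.requires_grad:
            w.accumulate_grad((xf.T @ dyf).reshape(C, O, 2, 2))
        if x.requires_grad or x._parents:
            dxf = dyf @ w.data.reshape(C, O * 4).T
            x.accumulate_grad(dxf.reshape(N, H, W, C).transpose(0, 3, 1, 2))
        if b is not None and b.requires_grad:
            b.accumulate_grad(dy.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return make_op(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, 0)

    def backward(dy):
        x.accumulate_grad(dy * mask)

    return make_op(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    z = x.data
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)

    def backward(dy):
        x.accumulate_grad(dy * out * (1.0 - out))

    return make_op(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add requires identical shapes")
    out = a.data + b.data

    def backward(dy):
        a.accumulate_grad(dy)
        b.accumulate_grad(dy)

    return make_op(out, (a, b), backward)


def scale(x: Tensor, c: float) -> Tensor:
    """Multiply by a constant (variance control after residual sums)."""
    c = float(c)
    out = x.data * c

    def backward(dy):
        x.accumulate_grad(dy * c)

    return make_op(out, (x,), backward)


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[1] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=1)

    def backward(dy):
        start = 0
        for t, c in zip(tensors, sizes):
            t.accumulate_grad(dy[:, start:start + c])
            start += c

    return make_op(out, tuple(tensors), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(3, 5))

    def backward(dy):
        mask = (xr == out[:, :, :, None, :, None])
        ties = mask.sum(axis=(3, 5), keepdims=True)
        dxr = mask * (dy[:, :, :, None, :, None] / ties)
        x.accumulate_grad(dxr.reshape(N, C, H, W))

    return make_op(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    f = int(factor)
    out = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)

    def backward(dy):
        N, C, Hf, Wf = dy.shape
        x.accumulate_grad(dy.reshape(N, C, Hf // f, f, Wf // f, f).sum(axis=(3, 5)))

    return make_op(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(dy):
        x.accumulate_grad(np.broadcast_to(dy / (H * W), x.data.shape).copy())

    return make_op(out, (x,), backward)


def broadcast_hw(x: Tensor, h: int, w: int) -> Tensor:
    """Tile a (N, C, 1, 1) tensor to (N, C, h, w)."""
    if x.data.shape[2:] != (1, 1):
        raise ValueError("broadcast_hw expects spatial shape (1, 1)")
    out = np.broadcast_to(x.data, x.data.shape[:2] + (h, w)).copy()

    def backward(dy):
        x.accumulate_grad(dy.sum(axis=(2, 3), keepdims=True))

    return make_op(out, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logits.

    Identical in value to the pixel-wise cross-entropy on sigmoid
    probabilities, but with the fused, saturation-free gradient.
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    if y.shape != z.shape:
        raise ValueError("logits/targets shape mismatch")
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = np.asarray(loss.mean(), dtype=z.dtype)

    def backward(dy):
        p = np.empty_like(z)
        pos = z >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        p[~pos] = ez / (1.0 + ez)
        logits.accumulate_grad((p - y) * (dy / z.size))

    return make_op(out, (logits,), backward)
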