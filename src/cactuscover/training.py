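"""Training loop: pixel-wise cross-entropy, Adam, best-validation
checkpointing.

The loss is mean binary cross-entropy over pixels; internally the update
uses the numerically fused logits form (identical value, saturation-free
gradient), while :func:`pixel_cross_entropy` is the probability-space
definition used for reporting and testing.  After every epoch the model is
scored on the validation tiles by pooled IoU at threshold 0.5, and the
parameters of the best-validation epoch (ties broken by lower validation
loss) are the ones returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ConfigurationError, InvalidParameterError
from .models import SegModel
from .nn import Adam, ops
from .nn.tensor import no_grad
from .tiling import DatasetSplit

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    threshold: float = 0.5         # binarisation cut for validation IoU
    early_stop_patience: int | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidParameterError("epochs and batch_size must be >= 1")
        if not (self.learning_rate > 0):
            raise InvalidParameterError("learning_rate must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    best_epoch: int = 0            # 1-based
    best_val_iou: float = 0.0


def pixel_cross_entropy(prob, mask) -> float:
    """Mean over pixels of -[y log p + (1-y) log(1-p)], p clipped to
    [1e-7, 1-1e-7]."""
    p = np.asarray(getattr(prob, "values", prob), dtype=np.float64)
    y = np.asarray(getattr(mask, "values", mask), dtype=np.float64)
    if p.shape != y.shape:
        raise AlignmentError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def _tiles_to_arrays(tiles):
    imgs = np.stack([t.model_image for t in tiles]).astype(np.float32) / 255.0
    masks = np.stack([t.model_mask for t in tiles]).astype(np.float32)
    return imgs, masks


def _evaluate(model: SegModel, imgs, masks, batch_size: int, threshold: float):
    """Validation loss (mean BCE) and pooled IoU at the given threshold."""
    losses = []
    inter = union = 0
    with no_grad():
        for i in range(0, len(imgs), batch_size):
            xb, yb = imgs[i:i + batch_size], masks[i:i + batch_size]
            probs = model.predict_batch(xb)
            losses.append(pixel_cross_entropy(probs, yb) * len(xb))
            pred = probs >= threshold
            ref = yb >= 0.5
            inter += int(np.logical_and(pred, ref).sum())
            union += int(np.logical_or(pred, ref).sum())
    loss = float(np.sum(losses) / len(imgs))
    return loss, (inter / union if union else 1.0)


def train(model: SegModel, split: DatasetSplit, config: TrainConfig
          ) -> tuple[SegModel, TrainHistory]:
    """Fit ``model`` on the split's training tiles.

    Returns the model carrying the parameters of the best-validation-IoU
    epoch (not the last epoch) and the full per-epoch history.  Fully
    deterministic for fixed seeds: data order comes from ``config.seed``,
    initial weights from ``model.spec.seed``.
    """
    if not split.train_tiles:
        raise ConfigurationError("empty training set")
    if not split.validation_tiles:
        raise ConfigurationError("empty validation set (needed for "
                                 "best-epoch checkpointing)")
    rng = np.random.default_rng(config.seed)
    x_train, y_train = _tiles_to_arrays(split.train_tiles)
    x_val, y_val = _tiles_to_arrays(split.validation_tiles)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_state = model.state()
    best_iou = -1.0
    best_loss = np.inf
    since_best = 0

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward_logits(x_train[idx])
            loss = ops.bce_with_logits(logits, y_train[idx][:, None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(idx))
        history.train_loss.append(float(np.sum(epoch_losses) / len(order)))

        v_loss, v_iou = _evaluate(model, x_val, y_val,
                                  config.batch_size, config.threshold)
        history.val_loss.append(v_loss)
        history.val_iou.append(v_iou)

        if v_iou > best_iou or (v_iou == best_iou and v_loss < best_loss):
            best_iou, best_loss = v_iou, v_loss
            best_state = model.state()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if (config.early_stop_patience is not None
                    and since_best >= config.early_stop_patience):
                break

    history.best_val_iou = best_iou
    model.load_state(best_state)
    return model, history
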