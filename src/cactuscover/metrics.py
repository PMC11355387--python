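"""Vegetation-cover quantification and validation metrics.

Pixel counting, count-to-area conversion (area = count x pixel ground
area), intersection-over-union between binary masks,

    IoU = |P and R| / (|R| + |P| - |P and R|),

and root-mean-square error over paired observation vectors,

    RMSE = sqrt(mean((y_i - yhat_i)^2)).

The area report mirrors a field-survey comparison table: one row per model
with pixel count, area in m^2, mosaic-level IoU against the reference mask,
and RMSE over per-tile foreground counts, plus a reference row (IoU 1,
RMSE 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidParameterError
from .types import BinaryMask


@dataclass
class EvalMetrics:
    iou: float
    rmse: float
    n_units: int

    def __post_init__(self):
        if not (0.0 <= self.iou <= 1.0):
            raise InvalidParameterError("iou must lie in [0, 1]")
        if self.rmse < 0:
            raise InvalidParameterError("rmse must be non-negative")


def count_foreground(mask: BinaryMask | np.ndarray) -> int:
    """Exact number of 1-pixels in a binary mask."""
    v = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    if not np.isin(np.unique(v), (0, 1)).all():
        raise InvalidParameterError("mask must be binary")
    return int(v.sum(dtype=np.int64))


def area_from_count(pixel_count: int, pixel_area_m2: float) -> float:
    """Convert a foreground pixel count to ground area in m^2."""
    if pixel_count < 0:
        raise InvalidParameterError("pixel_count must be non-negative")
    if not (pixel_area_m2 > 0):
        raise InvalidParameterError("pixel_area_m2 must be positive")
    return pixel_count * pixel_area_m2


def iou(pred: BinaryMask | np.ndarray, ref: BinaryMask | np.ndarray) -> float:
    """Intersection over union of two aligned binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on
    'nothing there' rather than 0/0).
    """
    p = pred.values if isinstance(pred, BinaryMask) else np.asarray(pred)
    r = ref.values if isinstance(ref, BinaryMask) else np.asarray(ref)
    if p.shape != r.shape:
        raise AlignmentError(f"mask shapes differ: {p.shape} vs {r.shape}")
    for v in (p, r):
        if not np.isin(np.unique(v), (0, 1)).all():
            raise InvalidParameterError("masks must be binary")
    inter = int(np.logical_and(p, r).sum(dtype=np.int64))
    union = int(p.sum(dtype=np.int64)) + int(r.sum(dtype=np.int64)) - inter
    if union == 0:
        return 1.0
    return inter / union


def rmse(observed, predicted) -> float:
    """Root-mean-square error between two equal-length vectors."""
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size == 0:
        raise InvalidParameterError("rmse needs at least one observation")
    if y.shape != yhat.shape:
        raise InvalidParameterError(
            f"length mismatch: {y.size} observed vs {yhat.size} predicted")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class AreaReport:
    """Per-model vegetation-cover table with a reference row."""

    table: pd.DataFrame          # columns: model, pixel_count, area_m2, iou, rmse
    pixel_area_m2: float

    def __str__(self) -> str:
        df = self.table.copy()
        df["area_m2"] = df["area_m2"].map(lambda v: f"{v:.4f}")
        df["iou"] = df["iou"].map(lambda v: f"{v:.4f}")
        df["rmse"] = df["rmse"].map(lambda v: f"{v:.4f}")
        return df.to_string(index=False)


def build_area_report(predictions: dict, reference: BinaryMask,
                      pixel_area_m2: float,
                      per_tile_counts: dict | None = None) -> AreaReport:
    """Tabulate model predictions against a reference mask.

    ``predictions`` maps model name -> BinaryMask (or MosaicPrediction-like
    object with a ``full_mask`` attribute) aligned with ``reference``.
    ``per_tile_counts`` optionally maps model name -> (predicted per-tile
    foreground counts, reference per-tile counts) used for the RMSE column;
    models without an entry get RMSE over the single mosaic-level count.
    """
    rows = []
    ref_count = count_foreground(reference)
    for name, pred in predictions.items():
        mask = getattr(pred, "full_mask", pred)
        if mask.shape != reference.shape:
            raise AlignmentError(
                f"prediction {name!r} shape {mask.shape} != "
                f"reference {reference.shape}")
        cnt = count_foreground(mask)
        if per_tile_counts and name in per_tile_counts:
            pred_counts, ref_counts = per_tile_counts[name]
            err = rmse(ref_counts, pred_counts)
            n_units = len(np.atleast_1d(np.asarray(pred_counts)))
        else:
            err = rmse([ref_count], [cnt])
            n_units = 1
        rows.append({
            "model": name, "pixel_count": cnt,
            "area_m2": area_from_count(cnt, pixel_area_m2),
            "iou": iou(mask, reference), "rmse": err, "n_units": n_units,
        })
    rows.append({
        "model": "reference", "pixel_count": ref_count,
        "area_m2": area_from_count(ref_count, pixel_area_m2),
        "iou": 1.0, "rmse": 0.0, "n_units": 0,
    })
    return AreaReport(table=pd.DataFrame(rows), pixel_area_m2=pixel_area_m2)
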