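"""Segmentation scoring, inter-observer agreement and mean grayscale values.

Scores follow the usual binary-segmentation definitions: precision
P = TP/(TP+FP), recall R = TP/(TP+FN), IoU = TP/(TP+FP+FN), pixel accuracy
PA = (TP+TN)/total and dice = 2TP/(2TP+FP+FN). Empty-denominator cases use
the identity-consistent convention: a pair of empty masks scores 1, an
empty prediction against a nonempty truth (or vice versa) scores 0.

Agreement between mask sources (a model's detection results and several
expert annotators) is reported pairwise. Pair metrics are macro-averaged —
computed per slice and averaged across slices — by default; micro (pooled
over pixels) is available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import LabelMask, VoxelGrid


@dataclass(frozen=True)
class SegMetrics:
    """Scores for one (prediction, truth) mask pair; all in [0, 1]."""

    precision: float
    recall: float
    iou: float
    pixel_accuracy: float
    dice: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "iou": self.iou,
            "pixel_accuracy": self.pixel_accuracy,
            "dice": self.dice,
        }


def _values(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.values
    return LabelMask(np.asarray(mask)).values


def confusion(pred, truth) -> tuple[int, int, int, int]:
    """Pixel counts (TP, FP, FN, TN); they always sum to the total count."""
    p, t = _values(pred), _values(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    p, t = p.astype(bool), t.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return tp, fp, fn, tn


def _ratio(num: int, den: int, empty_value: float) -> float:
    return num / den if den else empty_value


def _scores_from_counts(tp: int, fp: int, fn: int, tn: int) -> SegMetrics:
    both_empty = 1.0  # identity-consistent 0/0 convention
    return SegMetrics(
        precision=_ratio(tp, tp + fp, both_empty if fn == 0 else 0.0),
        recall=_ratio(tp, tp + fn, both_empty if fp == 0 else 0.0),
        iou=_ratio(tp, tp + fp + fn, both_empty),
        pixel_accuracy=_ratio(tp + tn, tp + fp + fn + tn, both_empty),
        dice=_ratio(2 * tp, 2 * tp + fp + fn, both_empty),
    )


def segmentation_scores(pred, truth) -> SegMetrics:
    """Precision, recall, IoU, pixel accuracy and dice for one mask pair."""
    return _scores_from_counts(*confusion(pred, truth))


def pairwise_agreement(
    sets: Mapping[str, Mapping[object, np.ndarray | LabelMask]],
    pooling: str = "macro",
) -> pd.DataFrame:
    """Pairwise agreement table over named mask collections.

    ``sets`` maps a source name (e.g. ``"DR"`` for detection results,
    ``"D1"``..``"D3"`` for annotators) to a mapping of slice identifier ->
    mask; all sources must cover identical slice identifiers. Returns a
    DataFrame with rows P, R, mIoU, mPA and one column per unordered source
    pair; within a pair the first-named source plays the prediction role
    (this is what makes the P and R rows asymmetric).
    """
    if pooling not in ("macro", "micro"):
        raise ValueError("pooling must be 'macro' or 'micro'")
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two mask sources")
    ids0 = set(sets[names[0]])
    for name in names[1:]:
        ids = set(sets[name])
        if ids != ids0:
            missing = sorted(map(str, ids0 ^ ids))
            raise ValueError(f"mismatched slice sets for {name!r}: {missing}")
    slice_ids = sorted(ids0, key=str)

    # detection results come first, mirroring the reporting convention
    ordered = sorted(names, key=lambda n: (n != "DR", n))
    table: dict[str, dict[str, float]] = {}
    for a, b in combinations(ordered, 2):
        if pooling == "macro":
            per_slice = [
                segmentation_scores(sets[a][sid], sets[b][sid]).as_dict()
                for sid in slice_ids
            ]
            agg = {k: float(np.mean([s[k] for s in per_slice])) for k in per_slice[0]}
        else:
            counts = np.sum(
                [confusion(sets[a][sid], sets[b][sid]) for sid in slice_ids], axis=0)
            agg = _scores_from_counts(*map(int, counts)).as_dict()
        table[f"{a}-{b}"] = {
            "P": agg["precision"],
            "R": agg["recall"],
            "mIoU": agg["iou"],
            "mPA": agg["pixel_accuracy"],
        }
    return pd.DataFrame(table).loc[["P", "R", "mIoU", "mPA"]]


def mean_grayscale(grid: VoxelGrid, mask: LabelMask) -> tuple[list[float], float]:
    """Mean grayscale value (mGV) inside a segmented tunnel.

    Returns the per-slice mGVs (slices whose mask is empty are skipped) and
    the sequence mGV, the unweighted mean of the per-slice values — one
    number summarizing the bone distribution across the whole tunnel.
    """
    values = _values(mask)
    if values.shape != grid.shape:
        raise ValueError(f"shape mismatch: mask {values.shape} vs grid {grid.shape}")
    per_slice: list[float] = []
    for sl, msk in zip(grid.intensities, values):
        if msk.any():
            per_slice.append(float(sl[msk.astype(bool)].mean()))
    if not per_slice:
        raise ValueError("no tunnel voxels: mask is empty on every slice")
    return per_slice, float(np.mean(per_slice))


def mean_grayscale_weighted(grid: VoxelGrid, mask: LabelMask) -> float:
    """Voxel-weighted alternative: mean intensity over all masked voxels."""
    values = _values(mask)
    if values.shape != grid.shape:
        raise ValueError("shape mismatch")
    sel = values.astype(bool)
    if not sel.any():
        raise ValueError("no tunnel voxels: mask is empty")
    return float(grid.intensities[sel].mean())
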