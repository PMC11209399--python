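"""Segmentation accuracy against ground truth.

Three layers of evaluation:

* pixel level — the Dice coefficient 2|P∩G| / (|P|+|G|);
* object level — one-to-one matching of predicted to ground-truth
  instances (greedy, by descending overlap; default criterion IoU ≥ 0.5)
  giving precision, recall and F1 of nucleus detection;
* parameter level — RMSE between algorithmic and ground-truth values of a
  morphometric parameter across cases, and the RMSE-to-range ratio, which
  scales the error by the spread (max − min) of the ground-truth values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MatchCriterion = Literal["iou", "centroid"]


@dataclass(frozen=True)
class SegmentationQuality:
    dice: float
    f1: float
    precision: float
    recall: float
    n_matches: int
    n_pred: int
    n_gt: int


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Pixel-overlap Dice coefficient; 1 when both masks are empty."""
    p = np.asarray(pred) > 0
    g = np.asarray(gt) > 0
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def _overlap_table(pred: np.ndarray, gt: np.ndarray) -> dict[tuple[int, int], int]:
    """Intersection pixel counts for every (pred label, gt label) pair."""
    both = (pred > 0) & (gt > 0)
    if not both.any():
        return {}
    pairs = np.stack([pred[both], gt[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return {(int(p), int(g)): int(c) for (p, g), c in zip(uniq, counts)}


def match_objects(
    pred: np.ndarray,
    gt: np.ndarray,
    criterion: MatchCriterion = "iou",
    iou_threshold: float = 0.5,
) -> SegmentationQuality:
    """Object-level detection quality via greedy one-to-one matching.

    Candidate (pred, gt) pairs are ranked by descending IoU and accepted
    greedily, each instance matched at most once.  Under the default
    ``"iou"`` criterion a pair is eligible when IoU ≥ ``iou_threshold``;
    under ``"centroid"`` when the ground-truth centroid falls inside the
    predicted object.  Precision = matches / n_pred, recall =
    matches / n_gt, F1 their harmonic mean.  With neither predictions nor
    truth present, all metrics are 1 by convention.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")

    pred_sizes = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    gt_sizes = dict(zip(*np.unique(gt[gt > 0], return_counts=True)))
    n_pred, n_gt = len(pred_sizes), len(gt_sizes)
    d = dice(pred, gt)

    if n_pred == 0 and n_gt == 0:
        logger.info("empty prediction and truth: metrics 1 by convention")
        return SegmentationQuality(1.0, 1.0, 1.0, 1.0, 0, 0, 0)

    candidates = []
    for (pl, gl), inter in _overlap_table(pred, gt).items():
        union = pred_sizes[pl] + gt_sizes[gl] - inter
        iou = inter / union
        if criterion == "iou":
            eligible = iou >= iou_threshold
        elif criterion == "centroid":
            rows, cols = np.nonzero(gt == gl)
            cr, cc = int(round(rows.mean())), int(round(cols.mean()))
            eligible = pred[cr, cc] == pl
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if eligible:
            candidates.append((iou, pl, gl))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    n_matches = 0
    for _, pl, gl in candidates:
        if pl in used_p or gl in used_g:
            continue
        used_p.add(pl)
        used_g.add(gl)
        n_matches += 1

    precision = n_matches / n_pred if n_pred else 0.0
    recall = n_matches / n_gt if n_gt else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return SegmentationQuality(d, f1, precision, recall, n_matches, n_pred, n_gt)


def rmse(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared error over paired parameter values."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("need at least one (predicted, truth) pair of equal length")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def rmse_to_range(predicted: np.ndarray, truth: np.ndarray) -> float:
    """RMSE scaled by the range (max − min) of the ground-truth values."""
    t = np.asarray(truth, dtype=float)
    rng = float(np.ptp(t))
    if rng <= 0:
        raise ValueError("ground-truth range must be positive")
    return rmse(predicted, truth) / rng


def quality_table(per_image: dict[str, SegmentationQuality]) -> pd.DataFrame:
    """One row per image plus a pooled-mean aggregate row."""
    rows = []
    for image_id, q in per_image.items():
        rows.append({"image_id": image_id, "dice": q.dice, "f1": q.f1,
                     "precision": q.precision, "recall": q.recall,
                     "n_matches": q.n_matches, "n_pred": q.n_pred, "n_gt": q.n_gt})
    df = pd.DataFrame(rows)
    if len(df):
        agg = df[["dice", "f1", "precision", "recall"]].mean().to_dict()
        agg.update({"image_id": "mean", "n_matches": df.n_matches.sum(),
                    "n_pred": df.n_pred.sum(), "n_gt": df.n_gt.sum()})
        df = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
    return df
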