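"""Pixel- and object-level scoring of predicted masks.

Pixel metrics are the usual confusion-matrix quantities. Object metrics and
the aggregated Jaccard index (AJI) operate on 4-connected component
labelings: AJI follows the standard greedy formulation — each ground-truth
object is matched to the available prediction object of highest IoU
(ground truth processed in ascending label order, ties broken by the lower
prediction label, each prediction usable once); matched intersections and
unions accumulate, and every unmatched prediction's area is added to the
union sum.

Degenerate cases: a ratio metric whose denominator is empty is 1 when both
masks are empty (nothing to find, nothing found) and 0 when only one side
is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ComponentLabeling, label_components
from .segmentation import predict_mask

__all__ = ["PixelMetrics", "ObjectMetrics", "AJIResult",
           "pixel_metrics", "aji", "object_pr", "evaluate_split"]


@dataclass
class PixelMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    dice: float
    iou: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class ObjectMetrics:
    precision: float
    recall: float
    matched: int
    unmatched_pred: int
    unmatched_gt: int


@dataclass
class AJIResult:
    aji: float
    intersection_sum: int
    union_sum: int


def _safe_div(num, den, both_empty):
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def pixel_metrics(pred_mask, gt_mask) -> PixelMetrics:
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    both_empty = (tp + fp + fn) == 0
    return PixelMetrics(
        accuracy=(tp + tn) / pred.size,
        sensitivity=_safe_div(tp, tp + fn, both_empty),
        specificity=_safe_div(tn, tn + fp, (tn + fp) == 0),
        dice=_safe_div(2 * tp, 2 * tp + fp + fn, both_empty),
        iou=_safe_div(tp, tp + fp + fn, both_empty),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def _as_labeling(x) -> ComponentLabeling:
    if isinstance(x, ComponentLabeling):
        return x
    return label_components(np.asarray(x))


def _overlap_table(pred_map, gt_map, n_pred, n_gt):
    """Sparse intersection counts {(gt_label, pred_label): pixels}."""
    both = (pred_map > 0) & (gt_map > 0)
    pairs = gt_map[both].astype(np.int64) * (n_pred + 1) + pred_map[both]
    counts = np.bincount(pairs, minlength=0)
    table = {}
    for code in np.flatnonzero(counts):
        table[(code // (n_pred + 1), code % (n_pred + 1))] = int(counts[code])
    return table


def aji(pred_labeling, gt_labeling) -> AJIResult:
    """Aggregated Jaccard index of a predicted vs reference instance labeling."""
    pred = _as_labeling(pred_labeling)
    gt = _as_labeling(gt_labeling)
    pred_areas = np.bincount(pred.label_map.ravel(),
                             minlength=pred.n_components + 1)
    gt_areas = np.bincount(gt.label_map.ravel(), minlength=gt.n_components + 1)
    overlaps = _overlap_table(pred.label_map, gt.label_map,
                              pred.n_components, gt.n_components)

    used = np.zeros(pred.n_components + 1, dtype=bool)
    inter_sum = 0
    union_sum = 0
    for g in range(1, gt.n_components + 1):
        best_iou, best_j, best_inter = -1.0, 0, 0
        for (gg, j), inter in overlaps.items():
            if gg != g or used[j]:
                continue
            iou = inter / (gt_areas[g] + pred_areas[j] - inter)
            if iou > best_iou or (iou == best_iou and j < best_j):
                best_iou, best_j, best_inter = iou, j, inter
        if best_j:
            used[best_j] = True
            inter_sum += best_inter
            union_sum += int(gt_areas[g] + pred_areas[best_j] - best_inter)
        else:
            union_sum += int(gt_areas[g])
    union_sum += int(pred_areas[1:][~used[1:]].sum())
    if union_sum == 0:
        return AJIResult(aji=1.0, intersection_sum=0, union_sum=0)
    return AJIResult(aji=inter_sum / union_sum,
                     intersection_sum=inter_sum, union_sum=union_sum)


def object_pr(pred_labeling, gt_labeling, min_iou: float = 0.0) -> ObjectMetrics:
    """Object-level precision/recall under one-to-one greedy overlap matching.

    Candidate pairs need >= 1 pixel of overlap (and IoU > ``min_iou`` when
    set); pairs are matched greedily by descending overlap size.
    """
    pred = _as_labeling(pred_labeling)
    gt = _as_labeling(gt_labeling)
    overlaps = _overlap_table(pred.label_map, gt.label_map,
                              pred.n_components, gt.n_components)
    if min_iou > 0.0:
        pred_areas = np.bincount(pred.label_map.ravel(),
                                 minlength=pred.n_components + 1)
        gt_areas = np.bincount(gt.label_map.ravel(),
                               minlength=gt.n_components + 1)
        overlaps = {
            (g, j): inter for (g, j), inter in overlaps.items()
            if inter / (gt_areas[g] + pred_areas[j] - inter) > min_iou
        }
    order = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
    gt_used, pred_used = set(), set()
    matched = 0
    for (g, j), _ in order:
        if g in gt_used or j in pred_used:
            continue
        gt_used.add(g)
        pred_used.add(j)
        matched += 1
    both_empty = pred.n_components == 0 and gt.n_components == 0
    return ObjectMetrics(
        precision=_safe_div(matched, pred.n_components, both_empty),
        recall=_safe_div(matched, gt.n_components, both_empty),
        matched=matched,
        unmatched_pred=pred.n_components - matched,
        unmatched_gt=gt.n_components - matched,
    )


def evaluate_pairs(pairs) -> dict:
    """Micro-averaged metrics over (pred_mask, gt_mask) pairs."""
    tp = fp = fn = tn = 0
    matched = n_pred = n_gt = 0
    inter_sum = union_sum = 0
    for pred, gt in pairs:
        pm = pixel_metrics(pred, gt)
        tp, fp, fn, tn = tp + pm.tp, fp + pm.fp, fn + pm.fn, tn + pm.tn
        om = object_pr(pred, gt)
        matched += om.matched
        n_pred += om.matched + om.unmatched_pred
        n_gt += om.matched + om.unmatched_gt
        aj = aji(pred, gt)
        inter_sum += aj.intersection_sum
        union_sum += aj.union_sum
    total = tp + fp + fn + tn
    both_empty = (tp + fp + fn) == 0
    return {
        "Accuracy": (tp + tn) / total if total else 1.0,
        "Sensitivity": _safe_div(tp, tp + fn, both_empty),
        "Specificity": _safe_div(tn, tn + fp, (tn + fp) == 0),
        "Dice": _safe_div(2 * tp, 2 * tp + fp + fn, both_empty),
        "IoU": _safe_div(tp, tp + fp + fn, both_empty),
        "AJI": _safe_div(inter_sum, union_sum, union_sum == 0),
        "Precision": _safe_div(matched, n_pred, n_pred == 0 and n_gt == 0),
        "Recall": _safe_div(matched, n_gt, n_pred == 0 and n_gt == 0),
    }


def evaluate_split(models: dict, patches, threshold: float = 0.5,
                   input_size: int | None = None) -> pd.DataFrame:
    """One row of pooled (micro-averaged) metrics per marker.

    ``models`` maps marker -> SegmentationModel; only markers present in
    both ``models`` and ``patches`` are scored.
    """
    if not patches:
        raise ValueError("empty evaluation set")
    rows = []
    for marker, model in sorted(models.items()):
        subset = [p for p in patches if p.marker == marker]
        if not subset:
            continue
        pairs = ((predict_mask(model, p.image, threshold,
                               input_size=input_size), p.mask)
                 for p in subset)
        rows.append({"marker": marker, "n_patches": len(subset),
                     **evaluate_pairs(pairs)})
    return pd.DataFrame(rows)
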