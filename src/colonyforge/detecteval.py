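"""Counting-evaluation metrics and per-colony size statistics.

Counting performance is scored with confusion counts in which the
true-negative cell is fixed at zero: background is not a countable
object, so there is nothing to correctly reject. The derived metrics are

    ACC = (TN + TP) / (TN + TP + FN + FP) = TP / (TP + FP + FN)
    TPR = TP / (TP + FN)
    FNR = FN / (TP + FN)

so TPR + FNR = 1 exactly and ACC <= TPR with equality iff FP = 0.

Matching predictions to ground truth needs an explicit rule (counting
papers rarely state one); two are provided: greedy one-to-one IoU
matching at a threshold (standard detection practice), and center-in-box
matching for centroid-only counters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import BoxAnnotation
from .thresholdcount import Detection


class UndefinedMetricError(ZeroDivisionError):
    """Metrics are undefined (no positives anywhere)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    acc: float
    tpr: float
    fnr: float

    def as_percentages(self, decimals: int = 1) -> tuple[float, float, float]:
        """(ACC, TPR, FNR) as percentages rounded for reporting."""
        return tuple(round(100.0 * v, decimals)
                     for v in (self.acc, self.tpr, self.fnr))


@dataclass(frozen=True)
class SizeStats:
    """Per-box width/height/area plus an area histogram.

    Histogram bins are half-open ``[edge_i, edge_{i+1})``; areas outside
    the outermost edges are not counted, so the counts sum to the box
    count whenever the edges cover the data range.
    """

    widths: np.ndarray
    heights: np.ndarray
    areas: np.ndarray
    bin_edges: np.ndarray
    histogram: np.ndarray


def match_detections(predicted: list[Detection],
                     truth: list[BoxAnnotation],
                     rule: str = "iou-greedy",
                     iou_threshold: float = 0.5) -> ConfusionCounts:
    """One-to-one matching of detections to ground-truth boxes.

    ``iou-greedy``: all (prediction, truth) pairs with IoU >= threshold
    are sorted by IoU descending (ties broken by indices) and accepted
    greedily, each prediction and truth at most once. ``center-in-box``:
    each prediction, in order, claims the unmatched truth box containing
    its centroid (nearest box centre on ambiguity). TP = matches,
    FP = unmatched predictions, FN = unmatched truths, TN = 0.
    """
    if rule not in ("iou-greedy", "center-in-box"):
        raise ValueError(f"unknown matching rule {rule!r}")
    matched_pred: set[int] = set()
    matched_truth: set[int] = set()
    if rule == "iou-greedy":
        pairs = [(p.box.iou(t), i, j)
                 for i, p in enumerate(predicted)
                 for j, t in enumerate(truth)]
        pairs = [(v, i, j) for v, i, j in pairs if v >= iou_threshold]
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        for _, i, j in pairs:
            if i not in matched_pred and j not in matched_truth:
                matched_pred.add(i)
                matched_truth.add(j)
    else:
        for i, p in enumerate(predicted):
            cx, cy = p.centroid
            candidates = [j for j, t in enumerate(truth)
                          if j not in matched_truth
                          and t.contains_point(cx, cy)]
            if candidates:
                j = min(candidates, key=lambda j: (
                    (truth[j].center[0] - cx) ** 2
                    + (truth[j].center[1] - cy) ** 2, j))
                matched_pred.add(i)
                matched_truth.add(j)
    tp = len(matched_pred)
    return ConfusionCounts(tp=tp, fp=len(predicted) - tp,
                           fn=len(truth) - len(matched_truth))


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """ACC/TPR/FNR from confusion counts (TN fixed at 0)."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tp + fn == 0:
        raise UndefinedMetricError(
            "TPR/FNR undefined: no positive ground truth (TP + FN = 0)")
    denom = tn + tp + fn + fp
    return MetricSet(acc=(tn + tp) / denom,
                     tpr=tp / (tp + fn),
                     fnr=fn / (tp + fn))


def colony_size_stats(boxes: list[BoxAnnotation],
                      bin_edges) -> SizeStats:
    """Width/height/area per box and the histogram of areas.

    Width is ``x2 - x1``, height ``y2 - y1``, area their product — the
    size measures read straight off detection boxes.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be ascending with >= 2 entries")
    widths = np.array([b.width for b in boxes], dtype=float)
    heights = np.array([b.height for b in boxes], dtype=float)
    areas = widths * heights
    idx = np.digitize(areas, edges)  # bin i+1 covers [edge_i, edge_{i+1})
    hist = np.bincount(idx, minlength=len(edges) + 1)[1:len(edges)]
    return SizeStats(widths=widths, heights=heights, areas=areas,
                     bin_edges=edges,
                     histogram=hist.astype(int))
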