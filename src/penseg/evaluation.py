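"""Match detections against ground truth and compute panoptic metrics.

Predicted ellipses are rasterized individually (they may overlap slightly)
and matched one-to-one against the exclusive ground-truth instance map.  A
pair is a candidate match only when its mask IoU is *strictly* greater than
0.5; candidates are resolved greedily by descending IoU, which for
non-overlapping maps coincides with the optimal assignment (at most one
prediction can exceed IoU 0.5 per ground-truth segment).

Panoptic quality summarizes segmentation and detection in one number:

    PQ = sum of matched IoUs / (|TP| + 0.5 |FP| + 0.5 |FN|)

Precision, recall and F1 use the same TP/FP/FN sets.  Pixel-level quality
of the semantic maps is reported as Jaccard indices, and head-direction
quality as the fraction of true positives whose predicted orientation is
within 90 degrees (circular) of the annotated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ellipse import Ellipse, mask_iou, rasterize_ellipse
from .postprocess import Detection

__all__ = [
    "MatchReport",
    "MetricValues",
    "match_segments",
    "panoptic_quality",
    "detection_scores",
    "jaccard_accuracy",
    "orientation_accuracy",
    "evaluate_dataset",
]


@dataclass
class MatchReport:
    """One-to-one segment matches (IoU > 0.5) plus the unmatched leftovers."""

    matches: list[tuple[int, int, float]] = field(default_factory=list)  # (pred, gt, IoU)
    unmatched_pred: list[int] = field(default_factory=list)
    unmatched_gt: list[int] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    def merged(self, other: "MatchReport", pred_offset: int, gt_offset: int) -> "MatchReport":
        """Pool two reports (ids shifted so they stay unique across images)."""
        return MatchReport(
            matches=self.matches
            + [(p + pred_offset, g + gt_offset, i) for p, g, i in other.matches],
            unmatched_pred=self.unmatched_pred + [p + pred_offset for p in other.unmatched_pred],
            unmatched_gt=self.unmatched_gt + [g + gt_offset for g in other.unmatched_gt],
        )


@dataclass
class MetricValues:
    pq: float
    f1: float
    precision: float
    recall: float
    binary_jaccard: float
    categorical_jaccard: float
    orientation_accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pq": self.pq, "f1": self.f1, "precision": self.precision,
            "recall": self.recall, "binary_jaccard": self.binary_jaccard,
            "categorical_jaccard": self.categorical_jaccard,
            "orientation_accuracy": self.orientation_accuracy,
        }


def _pred_masks(pred, image_size) -> list[np.ndarray]:
    masks = []
    for item in pred:
        e = item.ellipse if isinstance(item, Detection) else item
        masks.append(rasterize_ellipse(e, image_size))
    return masks


def match_segments(pred, gt_instance_map: np.ndarray) -> MatchReport:
    """Match predicted ellipses (or a predicted instance map) to GT segments.

    ``pred`` may be a list of :class:`Detection`/:class:`Ellipse` or an
    integer instance map of the same shape as ``gt_instance_map``.  Returned
    ids are 0-based prediction indices and the GT map's instance ids.
    """
    gt = np.asarray(gt_instance_map)
    if isinstance(pred, np.ndarray) and pred.ndim == 2:
        if pred.shape != gt.shape:
            raise ValueError(f"map shapes differ: {pred.shape} vs {gt.shape}")
        pred_ids = [int(i) for i in np.unique(pred) if i != 0]
        pred_masks = [pred == i for i in pred_ids]
    else:
        pred_masks = _pred_masks(pred, gt.shape)
        pred_ids = list(range(len(pred_masks)))

    gt_ids = [int(i) for i in np.unique(gt) if i != 0]
    gt_masks = {g: gt == g for g in gt_ids}

    candidates = []
    for pi, pm in zip(pred_ids, pred_masks):
        for g in gt_ids:
            iou = mask_iou(pm, gt_masks[g])
            if iou > 0.5:
                candidates.append((iou, pi, g))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    report = MatchReport()
    used_p: set[int] = set()
    used_g: set[int] = set()
    for iou, pi, g in candidates:
        if pi in used_p or g in used_g:
            continue
        used_p.add(pi)
        used_g.add(g)
        report.matches.append((pi, g, iou))
    report.unmatched_pred = [p for p in pred_ids if p not in used_p]
    report.unmatched_gt = [g for g in gt_ids if g not in used_g]
    return report


def panoptic_quality(report: MatchReport) -> float:
    denom = report.tp + 0.5 * report.fp + 0.5 * report.fn
    if denom == 0:
        return 0.0
    return float(sum(iou for *_, iou in report.matches) / denom)


def detection_scores(report: MatchReport) -> tuple[float, float, float]:
    """(precision, recall, f1); each 0 when its denominator is 0."""
    tp, fp, fn = report.tp, report.fp, report.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def jaccard_accuracy(pred_map: np.ndarray, gt_map: np.ndarray, mode: str = "binary") -> float:
    """Jaccard index of two label maps.

    ``binary``: IoU of the foreground.  ``categorical``: unweighted mean of
    per-class IoU over classes present in either map.
    """
    pred_map = np.asarray(pred_map)
    gt_map = np.asarray(gt_map)
    if pred_map.shape != gt_map.shape:
        raise ValueError(f"map shapes differ: {pred_map.shape} vs {gt_map.shape}")
    if mode == "binary":
        return mask_iou(pred_map > 0, gt_map > 0)
    if mode != "categorical":
        raise ValueError(f"unknown mode {mode!r}")
    classes = sorted(set(np.unique(pred_map)) | set(np.unique(gt_map)))
    ious = [mask_iou(pred_map == c, gt_map == c) for c in classes]
    return float(np.mean(ious)) if ious else 0.0


def _circular_delta(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def orientation_accuracy(
    report: MatchReport, pred, gt_ellipses: dict[int, Ellipse]
) -> float:
    """Fraction of TPs whose predicted head direction is within 90 degrees.

    Unoriented predictions count as incorrect; TPs whose ground truth is
    itself unoriented are excluded.  Returns 0.0 when no TP has an oriented
    ground truth.
    """
    pred = list(pred)
    total = 0
    correct = 0
    for pi, g, _ in report.matches:
        gt_e = gt_ellipses.get(g)
        if gt_e is None or not gt_e.oriented:
            continue
        total += 1
        item = pred[pi]
        e = item.ellipse if isinstance(item, Detection) else item
        if e.oriented and _circular_delta(e.phi, gt_e.phi) <= 90.0:
            correct += 1
    return correct / total if total else 0.0


def evaluate_dataset(per_image: list[dict]) -> tuple[MetricValues, list[dict]]:
    """Pool per-image results into dataset-level metrics.

    Each entry of ``per_image`` must carry ``report`` (MatchReport), ``pred``
    (detections), ``gt_ellipses`` (id -> Ellipse), and may carry
    ``binary_jaccard`` / ``categorical_jaccard`` floats.  TP/FP/FN are pooled
    over images for PQ and F1 (set formulation); Jaccard indices are
    averaged per image.
    """
    pooled = MatchReport()
    p_off = g_off = 0
    orient_total = orient_correct = 0
    bj, cj, rows = [], [], []
    for entry in per_image:
        rep: MatchReport = entry["report"]
        precision, recall, f1 = detection_scores(rep)
        rows.append(
            {
                "image_id": entry.get("image_id", ""),
                "tp": rep.tp, "fp": rep.fp, "fn": rep.fn,
                "pq": panoptic_quality(rep), "f1": f1,
            }
        )
        gt_ell = entry["gt_ellipses"]
        pred = list(entry["pred"])
        for pi, g, _ in rep.matches:
            gt_e = gt_ell.get(g)
            if gt_e is None or not gt_e.oriented:
                continue
            orient_total += 1
            item = pred[pi]
            e = item.ellipse if isinstance(item, Detection) else item
            if e.oriented and _circular_delta(e.phi, gt_e.phi) <= 90.0:
                orient_correct += 1
        if "binary_jaccard" in entry:
            bj.append(entry["binary_jaccard"])
        if "categorical_jaccard" in entry:
            cj.append(entry["categorical_jaccard"])
        pooled = pooled.merged(rep, p_off, g_off)
        p_off += rep.tp + rep.fp
        g_off += max([g for _, g, _ in rep.matches] + rep.unmatched_gt, default=0) + 1
    precision, recall, f1 = detection_scores(pooled)
    metrics = MetricValues(
        pq=panoptic_quality(pooled),
        f1=f1,
        precision=precision,
        recall=recall,
        binary_jaccard=float(np.mean(bj)) if bj else 0.0,
        categorical_jaccard=float(np.mean(cj)) if cj else 0.0,
        orientation_accuracy=orient_correct / orient_total if orient_total else 0.0,
    )
    return metrics, rows
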