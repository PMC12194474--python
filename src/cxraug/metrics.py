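"""Instance-level segmentation evaluation: P/R/F1, AP, mAP over polygons.

Predictions are polygons with confidences; ground truth are polygons.
Overlap is measured as mask IoU: both polygons are rasterized at image
resolution and intersection/union pixel counts are taken. Matching is
class-wise greedy in descending confidence, each ground-truth region
matched at most once. AP uses 101-point (COCO-style) interpolation of the
precision–recall curve; mAP@0.5:0.95 averages AP over IoU thresholds 0.50
to 0.95 in 0.05 steps, then over classes.

Zero-denominator conventions: precision is 0 when there are no predictions
but ground truth exists; recall is 0 when there is ground truth and no true
positives; a class absent from both ground truth and predictions is
excluded from class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import PolygonAnnotation, denormalize_coords
from .geometry import rasterize_polygon

COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """A predicted polygon with a confidence score."""

    class_id: int
    vertices: np.ndarray  # normalized (n, 2)
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")
        ann = PolygonAnnotation(self.class_id, self.vertices)  # validates
        object.__setattr__(self, "vertices", ann.vertices)

    @property
    def annotation(self) -> PolygonAnnotation:
        return PolygonAnnotation(self.class_id, self.vertices)


@dataclass
class MatchResult:
    """Per-class TP/FP/FN counts plus per-detection flags (confidence order)."""

    tp: dict[int, int] = field(default_factory=dict)
    fp: dict[int, int] = field(default_factory=dict)
    fn: dict[int, int] = field(default_factory=dict)
    flags: dict[int, list[tuple[float, bool]]] = field(default_factory=dict)

    def classes(self) -> list[int]:
        return sorted(set(self.tp) | set(self.fp) | set(self.fn))


def iou(
    a: np.ndarray | PolygonAnnotation,
    b: np.ndarray | PolygonAnnotation,
    width: int,
    height: int,
) -> float:
    """Mask IoU of two normalized polygons at the given image resolution."""
    ma = _mask(a, width, height)
    mb = _mask(b, width, height)
    union = np.count_nonzero(ma | mb)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(ma & mb) / union)


def _mask(poly, width: int, height: int) -> np.ndarray:
    if isinstance(poly, (PolygonAnnotation, Detection)):
        poly = poly.vertices
    return rasterize_polygon(denormalize_coords(np.asarray(poly, float), width, height), width, height)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[PolygonAnnotation],
    iou_thr: float = 0.5,
    width: int = 800,
    height: int = 800,
) -> MatchResult:
    """Greedy class-wise matching of detections to ground truth.

    Detections are visited in descending confidence; each is a true positive
    iff its best-IoU still-unmatched same-class ground truth reaches
    ``iou_thr``. Every ground truth matches at most one detection.
    """
    result = MatchResult()
    classes = sorted({d.class_id for d in dets} | {g.class_id for g in gts})
    for cls in classes:
        cls_dets = sorted(
            (d for d in dets if d.class_id == cls), key=lambda d: -d.confidence
        )
        cls_gts = [g for g in gts if g.class_id == cls]
        gt_masks = [_mask(g, width, height) for g in cls_gts]
        matched = [False] * len(cls_gts)
        flags: list[tuple[float, bool]] = []
        tp = 0
        for det in cls_dets:
            dm = _mask(det, width, height)
            best_iou, best_j = 0.0, -1
            for j, gm in enumerate(gt_masks):
                if matched[j]:
                    continue
                union = np.count_nonzero(dm | gm)
                val = np.count_nonzero(dm & gm) / union if union else 0.0
                if val > best_iou:
                    best_iou, best_j = val, j
            hit = best_iou >= iou_thr and best_j >= 0
            if hit:
                matched[best_j] = True
                tp += 1
            flags.append((det.confidence, hit))
        result.tp[cls] = tp
        result.fp[cls] = len(cls_dets) - tp
        result.fn[cls] = len(cls_gts) - tp
        result.flags[cls] = flags
    return result


def precision_recall_f1(match: MatchResult) -> pd.DataFrame:
    """Per-class precision, recall and F1 from match counts.

    F1 = 2PR/(P+R), the harmonic mean, 0 when P + R = 0.
    """
    rows = {}
    for cls in match.classes():
        tp, fp, fn = match.tp[cls], match.fp[cls], match.fn[cls]
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        rows[cls] = {"precision": p, "recall": r, "f1": f1}
    return pd.DataFrame.from_dict(rows, orient="index")


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def average_precision(
    dets: Sequence[Detection],
    gts: Sequence[PolygonAnnotation],
    iou_thr: float = 0.5,
    class_id: int | None = None,
    width: int = 800,
    height: int = 800,
) -> float:
    """101-point interpolated AP for one class at one IoU threshold.

    Returns 0 when the class has neither ground truth nor detections (the
    caller excludes such classes from means).
    """
    if class_id is not None:
        dets = [d for d in dets if d.class_id == class_id]
        gts = [g for g in gts if g.class_id == class_id]
    n_gt = len(gts)
    if n_gt == 0:
        return 0.0
    match = match_detections(dets, gts, iou_thr, width, height)
    flags = sorted(
        (pair for cls_flags in match.flags.values() for pair in cls_flags),
        key=lambda t: -t[0],
    )
    if not flags:
        return 0.0
    tp_cum = np.cumsum([1 if hit else 0 for _, hit in flags])
    fp_cum = np.cumsum([0 if hit else 1 for _, hit in flags])
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # 101-point interpolation: mean of max precision at recall >= r
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r - 1e-12
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / 101.0


def mean_ap(
    dets: Sequence[Detection],
    gts: Sequence[PolygonAnnotation],
    thresholds: Sequence[float] = (0.5,),
    width: int = 800,
    height: int = 800,
) -> float:
    """Mean over classes (present in ground truth) of mean AP over thresholds."""
    if not len(thresholds):
        raise ValueError("thresholds must be non-empty")
    classes = sorted({g.class_id for g in gts})
    if not classes:
        return 0.0
    per_class = [
        np.mean([
            average_precision(dets, gts, thr, cls, width, height) for thr in thresholds
        ])
        for cls in classes
    ]
    return float(np.mean(per_class))


def evaluate_folder(
    pred_dir: str | Path,
    truth_dir: str | Path,
    class_names: Sequence[str],
    iou_thr: float = 0.5,
    coco_range: bool = False,
    width: int = 800,
    height: int = 800,
) -> pd.DataFrame:
    """Evaluate a directory of prediction files against ground truth labels.

    Prediction files use the polygon-label dialect with an optional trailing
    confidence per line (defaults to 1.0 when absent). Returns a table with
    one row per class present plus an ``all`` macro-average row, and columns
    precision, recall, f1, ap (at ``iou_thr``) and, with ``coco_range``,
    ap_coco averaged over IoU 0.50–0.95.
    """
    from .formats import read_label_file

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    all_dets: list[Detection] = []
    all_gts: list[PolygonAnnotation] = []
    agg = MatchResult()
    for truth_path in sorted(truth_dir.glob("*.txt")):
        gts = read_label_file(truth_path, classes=len(class_names))
        pred_path = pred_dir / truth_path.name
        dets = read_prediction_file(pred_path, classes=len(class_names)) if pred_path.exists() else []
        match = match_detections(dets, gts, iou_thr, width, height)
        for cls in match.classes():
            agg.tp[cls] = agg.tp.get(cls, 0) + match.tp[cls]
            agg.fp[cls] = agg.fp.get(cls, 0) + match.fp[cls]
            agg.fn[cls] = agg.fn.get(cls, 0) + match.fn[cls]
        all_dets.extend(dets)
        all_gts.extend(gts)
    prf = precision_recall_f1(agg)
    rows = {}
    for cls in prf.index:
        row = dict(prf.loc[cls])
        row["ap"] = average_precision(all_dets, all_gts, iou_thr, cls, width, height)
        if coco_range:
            row["ap_coco"] = float(
                np.mean([
                    average_precision(all_dets, all_gts, t, cls, width, height)
                    for t in COCO_THRESHOLDS
                ])
            )
        rows[class_names[cls]] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table = pd.concat([table.mean(axis=0).to_frame("all").T, table])
    return table


def read_prediction_file(path: str | Path, classes: int) -> list[Detection]:
    """Parse predictions: label lines with an optional trailing confidence."""
    from .formats import LabelFormatError

    dets = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        class_id = int(tokens[0])
        if not 0 <= class_id < classes:
            raise LabelFormatError(f"{path}:{lineno}: class id {class_id} out of range")
        rest = [float(t) for t in tokens[1:]]
        if len(rest) % 2 == 1:  # trailing confidence present
            conf, rest = rest[-1], rest[:-1]
        else:
            conf = 1.0
        if len(rest) < 6:
            raise LabelFormatError(f"{path}:{lineno}: fewer than 3 vertices")
        dets.append(Detection(class_id, np.array(rest).reshape(-1, 2), conf))
    return dets
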