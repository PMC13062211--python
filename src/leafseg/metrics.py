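"""Segmentation evaluation: overlap metrics and lesion-boundary geometry.

Overlap metrics (Dice, IoU, pixel accuracy, precision/recall/F1) follow the
standard confusion-count definitions.  Per class, with predicted pixel set P
and reference set G:

    Dice = 2|P∩G| / (|P|+|G|)        IoU = |P∩G| / |P∪G|

with the empty/empty convention -> 1.0 and zero-denominator P/R/F1 -> 0.0
(with a logged warning).  Aggregation over images is reported both micro
(confusion counts pooled over the whole test set) and macro (unweighted mean
over classes).

Lesion geometry compares per-lesion size estimates between prediction and
reference: connected components (8-connectivity, since serpentine mines are
thin and diagonally connected) are matched by maximal pixel overlap, and for
each reference lesion the equivalent diameter sqrt(4*area/pi) or the
marching-squares perimeter is compared; a reference lesion with no matching
predicted component contributes its full measurement as error (a missed
lesion).  The summary is the RMSE over all reference lesions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .synthetic import component_perimeter

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport", "GeometryResult", "dice", "iou", "pixel_accuracy",
    "precision_recall_f1", "evaluate_masks", "lesion_geometry_rmse",
]


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> None:
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"pred shape {pred.shape} != gt shape {gt.shape}")


def dice(pred: np.ndarray, gt: np.ndarray, class_id: int) -> float:
    """Dice overlap for one class; both masks empty -> 1.0."""
    _check_shapes(pred, gt)
    p = np.asarray(pred) == class_id
    g = np.asarray(gt) == class_id
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p & g).sum() / denom)


def iou(pred: np.ndarray, gt: np.ndarray, class_id: int) -> float:
    """Jaccard index for one class; both masks empty -> 1.0."""
    _check_shapes(pred, gt)
    p = np.asarray(pred) == class_id
    g = np.asarray(gt) == class_id
    union = (p | g).sum()
    if union == 0:
        return 1.0
    return float((p & g).sum() / union)


def pixel_accuracy(pred: np.ndarray, gt: np.ndarray) -> float:
    """Fraction of pixels with the correct class, all classes included."""
    _check_shapes(pred, gt)
    pred, gt = np.asarray(pred), np.asarray(gt)
    return float((pred == gt).mean())


_warned_zero_denominator = False


def _prf_from_counts(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    global _warned_zero_denominator
    if tp + fp == 0 or tp + fn == 0:
        if not _warned_zero_denominator:
            logger.warning("precision/recall undefined (no positives); reporting 0.0 "
                           "(further occurrences suppressed)")
            _warned_zero_denominator = True
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        return float(precision), float(recall), float(f1)
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return float(precision), float(recall), float(f1)


def precision_recall_f1(pred: np.ndarray, gt: np.ndarray,
                        class_id: int) -> tuple[float, float, float]:
    _check_shapes(pred, gt)
    p = np.asarray(pred) == class_id
    g = np.asarray(gt) == class_id
    tp = float((p & g).sum())
    fp = float((p & ~g).sum())
    fn = float((~p & g).sum())
    return _prf_from_counts(tp, fp, fn)


@dataclass
class GeometryResult:
    """Per-lesion size-error summary for one class.

    ``rmse`` is ``None`` when the reference contains no lesions of the class
    (explicitly distinct from a perfect score of 0).
    """

    mode: str
    class_id: int
    rmse: float | None
    n_lesions: int
    n_missed: int
    table: pd.DataFrame


@dataclass
class MetricReport:
    per_class: dict[int, dict[str, float]]
    micro: dict[str, float]
    macro: dict[str, float]
    geometry: dict[int, dict[str, GeometryResult]] = field(default_factory=dict)
    n_images: int = 0
    n_pixels: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, vals in self.per_class.items():
            rows.append({"scope": f"class_{cid}", **vals})
        rows.append({"scope": "micro", **self.micro})
        rows.append({"scope": "macro", **self.macro})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "micro": self.micro,
            "macro": self.macro,
            "n_images": self.n_images,
            "n_pixels": self.n_pixels,
            "geometry": {
                str(cid): {mode: {"rmse": g.rmse, "n_lesions": g.n_lesions,
                                  "n_missed": g.n_missed}
                           for mode, g in modes.items()}
                for cid, modes in self.geometry.items()
            },
        }
        return json.dumps(payload, indent=2)

    def save(self, path_prefix) -> None:
        self.to_frame().to_csv(f"{path_prefix}.csv", index=False)
        with open(f"{path_prefix}.json", "w") as fh:
            fh.write(self.to_json())
        for cid, modes in self.geometry.items():
            for mode, geo in modes.items():
                geo.table.to_csv(f"{path_prefix}_geometry_class{cid}_{mode}.csv",
                                 index=False)


def evaluate_masks(preds: list[np.ndarray], gts: list[np.ndarray],
                   class_ids: list[int]) -> MetricReport:
    """Pooled (micro) and unweighted class-mean (macro) metrics over a set."""
    if len(preds) != len(gts):
        raise ValueError(f"got {len(preds)} predictions but {len(gts)} references")
    counts = {cid: np.zeros(3) for cid in class_ids}   # tp, fp, fn per class
    correct = 0
    total = 0
    for pred, gt in zip(preds, gts):
        _check_shapes(pred, gt)
        pred, gt = np.asarray(pred), np.asarray(gt)
        correct += int((pred == gt).sum())
        total += pred.size
        for cid in class_ids:
            p = pred == cid
            g = gt == cid
            counts[cid] += ((p & g).sum(), (p & ~g).sum(), (~p & g).sum())

    per_class: dict[int, dict[str, float]] = {}
    for cid in class_ids:
        tp, fp, fn = counts[cid]
        denom_d = 2 * tp + fp + fn
        d = 1.0 if denom_d == 0 else 2 * tp / denom_d
        denom_u = tp + fp + fn
        j = 1.0 if denom_u == 0 else tp / denom_u
        p, r, f1 = _prf_from_counts(tp, fp, fn)
        per_class[cid] = {"dice": float(d), "iou": float(j),
                          "precision": p, "recall": r, "f1": f1}

    tp = sum(counts[c][0] for c in class_ids)
    fp = sum(counts[c][1] for c in class_ids)
    fn = sum(counts[c][2] for c in class_ids)
    micro_p, micro_r, micro_f1 = _prf_from_counts(tp, fp, fn)
    micro = {
        "dice": float(1.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)),
        "iou": float(1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)),
        "pixel_accuracy": correct / total if total else 1.0,
        "precision": micro_p, "recall": micro_r, "f1": micro_f1,
    }
    macro = {key: float(np.mean([per_class[c][key] for c in class_ids]))
             for key in ("dice", "iou", "precision", "recall", "f1")}
    macro["pixel_accuracy"] = micro["pixel_accuracy"]
    return MetricReport(per_class=per_class, micro=micro, macro=macro,
                        n_images=len(preds), n_pixels=total)


def _components(mask: np.ndarray, class_id: int) -> np.ndarray:
    return measure.label(np.asarray(mask) == class_id, connectivity=2)


def _measure(component: np.ndarray, mode: str) -> float:
    if mode == "diameter":
        return float(np.sqrt(4.0 * component.sum() / np.pi))
    if mode == "circumference":
        return component_perimeter(component)
    raise ValueError(f"mode must be 'diameter' or 'circumference', got {mode!r}")


def lesion_geometry_rmse(preds: list[np.ndarray], gts: list[np.ndarray],
                         class_id: int, mode: str = "diameter") -> GeometryResult:
    """RMSE of per-lesion size estimates for one class over an image set.

    Components are matched reference-to-prediction by maximal pixel overlap
    (greedy, largest-overlap first; ties broken toward the larger reference
    lesion).  Unmatched reference lesions count their full measurement as
    error.  Returns ``rmse=None`` when no reference lesions exist.
    """
    if len(preds) != len(gts):
        raise ValueError(f"got {len(preds)} predictions but {len(gts)} references")
    rows = []
    for img_idx, (pred, gt) in enumerate(zip(preds, gts)):
        _check_shapes(pred, gt)
        gt_lab = _components(gt, class_id)
        pred_lab = _components(pred, class_id)
        n_gt, n_pred = gt_lab.max(), pred_lab.max()
        if n_gt == 0:
            continue
        # overlap counts between every (gt, pred) component pair
        pairs = []
        for gi in range(1, n_gt + 1):
            gmask = gt_lab == gi
            garea = int(gmask.sum())
            overlaps = np.bincount(pred_lab[gmask], minlength=n_pred + 1)
            for pi in range(1, n_pred + 1):
                if overlaps[pi] > 0:
                    pairs.append((int(overlaps[pi]), garea, gi, pi))
        pairs.sort(key=lambda t: (t[0], t[1]), reverse=True)
        matched_g: dict[int, int] = {}
        used_p: set[int] = set()
        for _, _, gi, pi in pairs:
            if gi in matched_g or pi in used_p:
                continue
            matched_g[gi] = pi
            used_p.add(pi)
        for gi in range(1, n_gt + 1):
            gmeas = _measure(gt_lab == gi, mode)
            pi = matched_g.get(gi)
            pmeas = _measure(pred_lab == pi, mode) if pi is not None else 0.0
            rows.append({"image": img_idx, "gt_component": gi,
                         "pred_component": pi if pi is not None else -1,
                         "gt_measure": gmeas, "pred_measure": pmeas,
                         "error": pmeas - gmeas, "missed": pi is None})
    table = pd.DataFrame(rows, columns=["image", "gt_component", "pred_component",
                                        "gt_measure", "pred_measure", "error", "missed"])
    if table.empty:
        return GeometryResult(mode=mode, class_id=class_id, rmse=None,
                              n_lesions=0, n_missed=0, table=table)
    rmse = float(np.sqrt((table["error"] ** 2).mean()))
    return GeometryResult(mode=mode, class_id=class_id, rmse=rmse,
                          n_lesions=len(table), n_missed=int(table["missed"].sum()),
                          table=table)
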