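"""Segmentation and phenotype metrics.

Per-class one-vs-rest confusion counts feed intersection-over-union,
precision, recall and F1, macro-averaged over organ classes and reported as
percents.  Phenotype estimates are scored by mean relative error (MRE) and
organ-count recovery by the coefficient of determination R^2 and RMSE.

By default mIoU averages over the classes present in the ground truth, so a
period in which buds or bolls do not yet exist is not penalized for absent
classes; ``mode="all"`` averages over every class instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score

from .pointcloud_core import CLASS_NAMES, PointCloudError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative counts."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self):
        self.tp = np.asarray(self.tp, dtype=np.int64)
        self.fp = np.asarray(self.fp, dtype=np.int64)
        self.fn = np.asarray(self.fn, dtype=np.int64)
        if not (len(self.tp) == len(self.fp) == len(self.fn)):
            raise PointCloudError("confusion count arrays must share length")
        if (self.tp < 0).any() or (self.fp < 0).any() or (self.fn < 0).any():
            raise PointCloudError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def present(self) -> np.ndarray:
        """Classes present in the ground truth (tp + fn > 0)."""
        return (self.tp + self.fn) > 0


def confusion(pred_labels, true_labels, n_classes: int = 5) -> ConfusionCounts:
    """One-vs-rest counts; points with a negative true label are excluded."""
    pred = np.asarray(pred_labels, dtype=np.int64).ravel()
    true = np.asarray(true_labels, dtype=np.int64).ravel()
    if len(pred) != len(true):
        raise PointCloudError("pred and true label vectors differ in length")
    keep = true >= 0
    pred, true = pred[keep], true[keep]
    if (true >= n_classes).any():
        raise PointCloudError("true labels exceed n_classes")
    tp = np.empty(n_classes, dtype=np.int64)
    fp = np.empty(n_classes, dtype=np.int64)
    fn = np.empty(n_classes, dtype=np.int64)
    for c in range(n_classes):
        tp[c] = np.sum((pred == c) & (true == c))
        fp[c] = np.sum((pred == c) & (true != c))
        fn[c] = np.sum((pred != c) & (true == c))
    return ConfusionCounts(tp, fp, fn)


def miou(counts: ConfusionCounts, mode: str = "present") -> tuple[float, np.ndarray]:
    """Mean IoU (percent) and the per-class IoU array (nan where skipped).

    IoU_i = TP_i / (TP_i + FP_i + FN_i); the mean runs over classes present
    in the ground truth (default) or over all classes (``mode="all"``).
    """
    union = counts.tp + counts.fp + counts.fn
    iou = np.full(counts.n_classes, np.nan)
    nz = union > 0
    iou[nz] = counts.tp[nz] / union[nz]
    if mode == "present":
        sel = counts.present
    elif mode == "all":
        sel = np.ones(counts.n_classes, dtype=bool)
        iou = np.where(np.isnan(iou), 0.0, iou)
    else:
        raise PointCloudError(f"unknown miou mode {mode!r}")
    if not sel.any():
        raise PointCloudError("no classes present in ground truth")
    return float(100.0 * np.nanmean(iou[sel])), 100.0 * iou


def pr_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Macro precision, recall and F1 in percent.

    Zero-denominator classes score 0 (with a warning), matching the
    convention that an absent or never-predicted class contributes no credit.
    """
    prec = np.zeros(counts.n_classes)
    rec = np.zeros(counts.n_classes)
    f1 = np.zeros(counts.n_classes)
    for c in range(counts.n_classes):
        pd_ = counts.tp[c] + counts.fp[c]
        rd = counts.tp[c] + counts.fn[c]
        if pd_ == 0 or rd == 0:
            logger.warning("class %d has a zero denominator; scored 0", c)
        prec[c] = counts.tp[c] / pd_ if pd_ else 0.0
        rec[c] = counts.tp[c] / rd if rd else 0.0
        s = prec[c] + rec[c]
        f1[c] = 2 * prec[c] * rec[c] / s if s else 0.0
    sel = counts.present
    if not sel.any():
        sel = np.ones(counts.n_classes, dtype=bool)
    return (float(100 * prec[sel].mean()), float(100 * rec[sel].mean()),
            float(100 * f1[sel].mean()))


def mre(truth, estimates) -> float:
    """Mean relative error in percent: mean of |y - yhat| / y x 100."""
    y = np.asarray(truth, dtype=np.float64).ravel()
    yhat = np.asarray(estimates, dtype=np.float64).ravel()
    if len(y) != len(yhat) or len(y) == 0:
        raise PointCloudError("truth and estimates must be equal-length, non-empty")
    if np.any(y == 0):
        raise PointCloudError("relative error undefined for zero truth values")
    return float(np.mean(np.abs(y - yhat) / np.abs(y)) * 100.0)


def count_regression(true_counts, pred_counts) -> tuple[float, float]:
    """R^2 and RMSE of predicted organ counts against the truth."""
    y = np.asarray(true_counts, dtype=np.float64).ravel()
    yhat = np.asarray(pred_counts, dtype=np.float64).ravel()
    if len(y) != len(yhat) or len(y) < 2:
        raise PointCloudError("need at least 2 paired counts")
    if np.allclose(y, y[0]):
        raise PointCloudError("R^2 undefined: zero variance in true counts")
    return (float(r2_score(y, yhat)),
            float(np.sqrt(mean_squared_error(y, yhat))))


@dataclass
class MetricsReport:
    """Bundle of segmentation metrics (percents) plus optional regressions."""

    iou_per_class: dict
    mIoU: float
    mP: float
    mR: float
    mF1: float
    MRE: float | None = None
    r2: float | None = None
    rmse: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"mIoU": self.mIoU, "mP": self.mP, "mR": self.mR, "mF1": self.mF1,
             "iou_per_class": self.iou_per_class}
        for k in ("MRE", "r2", "rmse"):
            if getattr(self, k) is not None:
                d[k] = getattr(self, k)
        d.update(self.extra)
        return d


def segmentation_report(pred_labels, true_labels, n_classes: int = 5,
                        mode: str = "present") -> MetricsReport:
    """Full metric bundle for one prediction/truth label pair."""
    counts = confusion(pred_labels, true_labels, n_classes)
    m, per_class = miou(counts, mode=mode)
    mp, mr, mf1 = pr_f1(counts)
    per = {CLASS_NAMES.get(c, str(c)): (None if np.isnan(per_class[c])
                                        else float(per_class[c]))
           for c in range(n_classes)}
    return MetricsReport(iou_per_class=per, mIoU=m, mP=mp, mR=mr, mF1=mf1)


def write_report(report: MetricsReport, path, fmt: str | None = None) -> None:
    """Write a report as JSON or a delimited table (by file extension)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    d = report.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    elif fmt in ("csv", "tsv"):
        per = d.pop("iou_per_class")
        rows = [{"metric": k, "value": v} for k, v in d.items()]
        rows += [{"metric": f"iou_{k}", "value": v} for k, v in per.items()]
        pd.DataFrame(rows).to_csv(path, index=False,
                                  sep="\t" if fmt == "tsv" else ",")
    else:
        raise PointCloudError(f"unsupported report format {fmt!r}")
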