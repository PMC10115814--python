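"""Segmentation evaluation: confusion counts and the seven overlap metrics.

All metrics derive from pixel-level confusion counts between a binary
prediction and the ground-truth mask:

    IOU  = TP/(TP+FP+FN)          Dice = 2TP/(2TP+FP+FN)
    ACC  = (TP+TN)/total          Recall = TP/(TP+FN)
    Precision = TP/(TP+FP)        Specificity = TN/(TN+FP)
    F1 = 2·PR·RE/(PR+RE)

For counts from a single image F1 coincides with Dice and
Dice = 2·IOU/(1+IOU).  Dataset summaries report the per-image mean and
population standard deviation of each metric; the dataset-level F1 is
additionally computed as the harmonic mean of the *mean* precision and
*mean* recall, which is how per-cohort F1 columns are conventionally tabled
(it differs from the mean per-image Dice).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion",
           "metrics_from_counts", "harmonic_f1", "aggregate_reports",
           "write_report_csv"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    iou: float
    dice: float
    acc: float
    recall: float
    precision: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_NAMES = [f.name for f in fields(MetricReport)]


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts between two binary masks of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(
            f"prediction {pred.shape} and truth {truth.shape} differ")
    for name, arr in (("prediction", pred), ("truth", truth)):
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def _ratio(num: int, den: int) -> float:
    """Safe ratio: an empty denominator means the condition is vacuous, so
    the score is perfect iff the numerator side is also empty."""
    if den == 0:
        return 1.0 if num == 0 else 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricReport:
    pr = _ratio(c.tp, c.tp + c.fp)
    re = _ratio(c.tp, c.tp + c.fn)
    if pr + re == 0.0:
        f1 = 0.0 if (c.tp + c.fp + c.fn) else 1.0
    else:
        f1 = 2 * pr * re / (pr + re)
    return MetricReport(
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        acc=_ratio(c.tp + c.tn, c.total),
        recall=re,
        precision=pr,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
    )


def harmonic_f1(precision: float, recall: float) -> float:
    """Harmonic mean of a mean precision and mean recall (dataset-level F1)."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def aggregate_reports(reports: list[MetricReport]) -> dict:
    """Per-metric mean ± population std over images, plus dataset-level F1."""
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    table = {name: np.array([getattr(r, name) for r in reports])
             for name in METRIC_NAMES}
    summary = {
        "n": len(reports),
        "mean": {k: float(v.mean()) for k, v in table.items()},
        "std": {k: float(v.std()) for k, v in table.items()},
    }
    summary["dataset_f1"] = harmonic_f1(summary["mean"]["precision"],
                                        summary["mean"]["recall"])
    return summary


def format_summary(summary: dict) -> str:
    """Render a summary as 'metric mean ± std' lines."""
    lines = []
    for name in METRIC_NAMES:
        lines.append(f"{name:<12s} {summary['mean'][name]:.3f} "
                     f"± {summary['std'][name]:.3f}")
    lines.append(f"{'dataset_f1':<12s} {summary['dataset_f1']:.3f}")
    return "\n".join(lines)


def write_report_csv(path: str | Path, names: list[str],
                     counts: list[ConfusionCounts],
                     reports: list[MetricReport]) -> None:
    """One row per image (seven metrics + raw counts) and a summary row."""
    summary = aggregate_reports(reports)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image"] + METRIC_NAMES + ["tp", "fp", "fn", "tn"])
        for name, c, r in zip(names, counts, reports):
            writer.writerow(
                [name] + [f"{getattr(r, m):.6f}" for m in METRIC_NAMES]
                + [c.tp, c.fp, c.fn, c.tn])
        writer.writerow(
            ["mean±std"]
            + [f"{summary['mean'][m]:.3f} ± {summary['std'][m]:.3f}"
               for m in METRIC_NAMES] + ["", "", "", ""])
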