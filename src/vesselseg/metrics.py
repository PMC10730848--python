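"""Confusion counts and segmentation scores over binarised predictions.

Positive class is vessel (= 1).  The four scores::

    Dice = 2TP / (2TP + FP + FN)
    SE   = TP / (TP + FN)          (sensitivity / recall)
    SP   = TN / (FP + TN)          (specificity)
    Acc  = (TP + TN) / (TP + FP + FN + TN)

Aggregation over an image set is *micro*: confusion counts are summed over
all images first and the scores computed once from the sums; per-image
reports are retained so macro averages can be formed downstream.  A score
whose denominator is zero is reported as ``None`` ("undefined"), never
silently 0 or 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import FundusRecord, crop_to, pad_for_inference, preprocess_image


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class MetricsReport:
    dice: float | None
    se: float | None
    sp: float | None
    acc: float | None
    counts: ConfusionCounts
    n_images: int = 1
    per_image: list[tuple[str, "MetricsReport"]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "dice": self.dice, "se": self.se, "sp": self.sp, "acc": self.acc,
            "tp": self.counts.tp, "fp": self.counts.fp,
            "fn": self.counts.fn, "tn": self.counts.tn,
        }


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: pixel >= threshold -> 1."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0,1], got {threshold}")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0,1]")
    return (prob >= threshold).astype(np.int64)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1, found values {vals[:8]}")
    return arr.astype(bool)


def confusion(pred: np.ndarray, gt: np.ndarray,
              roi: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts of ``pred`` against ``gt`` (vessel = 1).

    With ``roi`` given, only pixels where the region mask is 1 are counted.
    """
    pred = _check_binary(pred, "pred")
    gt = _check_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if roi is not None:
        roi = _check_binary(roi, "roi")
        if roi.shape != gt.shape:
            raise ValueError(f"roi shape {roi.shape} != gt shape {gt.shape}")
        pred, gt = pred[roi], gt[roi]
    return ConfusionCounts(
        tp=int(np.sum(pred & gt)),
        fp=int(np.sum(pred & ~gt)),
        fn=int(np.sum(~pred & gt)),
        tn=int(np.sum(~pred & ~gt)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(counts: ConfusionCounts, n_images: int = 1) -> MetricsReport:
    """Dice/SE/SP/Acc from confusion counts; undefined ratios become None."""
    if counts.total == 0:
        raise ValueError("no pixels evaluated (all counts zero)")
    return MetricsReport(
        dice=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
        se=_ratio(counts.tp, counts.tp + counts.fn),
        sp=_ratio(counts.tn, counts.fp + counts.tn),
        acc=_ratio(counts.tp + counts.tn, counts.total),
        counts=counts,
        n_images=n_images,
    )


def evaluate_set(model, records: list[FundusRecord], threshold: float = 0.5,
                 roi: str | None = None, gt: str = "label") -> MetricsReport:
    """Segment every record and score micro-aggregated Dice/SE/SP/Acc.

    Each image is preprocessed, reflection-padded to a multiple of 8,
    segmented, cropped back and binarised; confusion counts are summed
    over all images and the scores computed once from the sums.  Per-image
    reports are kept in ``report.per_image``.

    ``roi="fov"`` restricts scoring to the field-of-view mask where one is
    present; ``gt="label2"`` scores against the second observer.
    """
    if not records:
        raise ValueError("cannot evaluate an empty record set")
    total = ConfusionCounts()
    per_image = []
    for rec in records:
        target = getattr(rec, gt)
        if target is None:
            raise ValueError(f"record {rec.id} has no {gt!r} annotation")
        prob = predict_record(model, rec)
        pred = binarize(prob, threshold)
        mask = rec.fov if (roi == "fov" and rec.fov is not None) else None
        counts = confusion(pred, target, mask)
        per_image.append((rec.id, compute_metrics(counts)))
        total = total + counts
    report = compute_metrics(total, n_images=len(records))
    report.per_image = per_image
    return report


def predict_record(model, rec: FundusRecord) -> np.ndarray:
    """Full-image vessel probability for one record (pad, predict, crop)."""
    gray = preprocess_image(rec.image)
    padded, spec = pad_for_inference(gray)
    prob = model.predict(padded[None, None])
    return np.asarray(crop_to(prob[0], spec))


def write_report(path, report: MetricsReport) -> None:
    """Write per-image rows plus an 'aggregate' row as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["id", "tp", "fp", "fn", "tn", "dice", "se", "sp", "acc"]

    def row(rid: str, rep: MetricsReport) -> dict:
        d = rep.as_dict()
        d["id"] = rid
        return {k: ("undefined" if d[k] is None else d[k]) for k in cols}

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for rid, rep in report.per_image:
            writer.writerow(row(rid, rep))
        writer.writerow(row("aggregate", report))


def read_report(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
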