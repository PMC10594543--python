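"""Segmentation agreement at the pixel level, the region level, and between
paired capillary variables (Bland-Altman).

Pixel-level metrics (accuracy, precision, recall, specificity, Dice, IoU)
punish thin-structure segmentations hard: a 1-2 px width error on a vessel a
few px wide wrecks the overlap even when the same capillary was found. The
region-level scheme is tolerant of boundary error: a ground-truth region
counts as TP if *any* of its pixels is predicted, FN if none is; a predicted
region disjoint from all ground-truth foreground is an FP. TP is thus
counted in ground-truth-region units and FP in predicted-region units —
mixed units, and precision = TP/(TP+FP) mixes them deliberately; there is no
region-level TN or IoU. Degenerate ratios (0/0) are reported as None, never
as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import validate_binary_mask
from .quantify import _STRUCTURES

__all__ = [
    "ConfusionCounts", "PixelMetricReport", "RegionMetricReport",
    "BlandAltmanResult", "pixel_confusion", "pixel_metrics",
    "region_confusion", "bland_altman", "average_reports",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class PixelMetricReport:
    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    dice: float | None
    iou: float | None


@dataclass
class RegionMetricReport:
    """Region-level counts and metrics; no TN and no IoU by design."""

    tp_regions: int
    fn_regions: int
    fp_regions: int
    precision: float | None
    recall: float | None
    dice: float | None


@dataclass
class BlandAltmanResult:
    """Limits of agreement: mean difference +- 1.96 sample SD (ddof=1)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    sign_convention: str
    means: np.ndarray | None = None  # per-pair (gt+pred)/2, for plotting
    diffs: np.ndarray | None = None


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = validate_binary_mask(pred)
    gt = validate_binary_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def _ratio(num: float, den: float) -> float | None:
    return num / den if den else None


def pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel cross-tabulation with foreground (255) as positive."""
    pred, gt = _check_pair(pred, gt)
    p = pred > 0
    g = gt > 0
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def pixel_metrics(c: ConfusionCounts) -> PixelMetricReport:
    if c.total <= 0:
        raise ValueError("empty confusion table")
    return PixelMetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
    )


def region_confusion(pred: np.ndarray, gt: np.ndarray,
                     connectivity: int = 8) -> RegionMetricReport:
    """Region-level TP/FN/FP for thin-structure-tolerant evaluation.

    TP: ground-truth regions with >= 1 predicted-foreground pixel.
    FN: ground-truth regions with none. FP: predicted regions disjoint from
    all ground-truth foreground. A predicted blob touching several GT
    regions makes each of them TP.
    """
    pred, gt = _check_pair(pred, gt)
    struct = _STRUCTURES[connectivity]
    gt_lab, n_gt = ndimage.label(gt > 0, structure=struct)
    pr_lab, n_pr = ndimage.label(pred > 0, structure=struct)

    hit_gt = np.unique(gt_lab[(pred > 0) & (gt_lab > 0)])
    tp = int(hit_gt.size)
    fn = n_gt - tp
    hit_pr = np.unique(pr_lab[(gt > 0) & (pr_lab > 0)])
    fp = n_pr - int(hit_pr.size)

    return RegionMetricReport(
        tp_regions=tp, fn_regions=fn, fp_regions=fp,
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        dice=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def bland_altman(gt, pred, sign: str = "pred_minus_gt") -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    Differences follow ``sign`` ("pred_minus_gt" or "gt_minus_pred"); limits
    of agreement are mean +- 1.96 sample standard deviations (ddof=1).
    """
    gt = np.asarray(gt, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if gt.shape != pred.shape or gt.ndim != 1:
        raise ValueError("gt and pred must be equal-length 1-D sequences")
    if gt.size < 2:
        raise ValueError("need n >= 2 pairs")
    if sign == "pred_minus_gt":
        diffs = pred - gt
    elif sign == "gt_minus_pred":
        diffs = gt - pred
    else:
        raise ValueError(f"unknown sign convention {sign!r}")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean, sd_diff=sd,
        loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
        n=int(gt.size), sign_convention=sign,
        means=(gt + pred) / 2.0, diffs=diffs,
    )


def average_reports(reports: list[PixelMetricReport]) -> PixelMetricReport:
    """Equal-weight average of per-image metric reports.

    Metrics are averaged across images (not pooled from summed confusion
    counts); None entries are excluded per metric, and a metric undefined in
    every image stays None.
    """
    if not reports:
        raise ValueError("no reports to average")

    def avg(name: str) -> float | None:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        return float(np.mean(vals)) if vals else None

    return PixelMetricReport(**{f: avg(f) for f in
                                ("accuracy", "precision", "recall",
                                 "specificity", "dice", "iou")})
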