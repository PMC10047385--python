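"""Multi-level evaluation: detection metrics, ROC/AUC, and ICC agreement.

Reporting follows three levels: whole-volume detection (is any at-risk
tissue present in the cube), per-B-scan detection, and pixel-wise
measurement of the segmented band.  Agreement between predicted and
ground-truth per-B-scan area percentages is summarised with a two-way
random-effects, absolute-agreement, single-measures intraclass correlation
(ICC(2,1)) — the standard form for method-versus-truth agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .core import ValidationError
from .harness import ScaleRecord, measure_area_pct

__all__ = [
    "EvalReport",
    "ICCResult",
    "confusion_metrics",
    "volume_detection_label",
    "roc_auc",
    "icc_agreement",
    "evaluate_run",
]


@dataclass
class EvalReport:
    """Confusion counts and derived metrics for one evaluation level."""

    level: str
    tp: int
    tn: int
    fp: int
    fn: int
    auc: float | None = None

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_pos if self.n_pos else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg if self.n_neg else float("nan")

    @property
    def single_class(self) -> bool:
        """True when the truth contains only one class (sens or spec undefined)."""
        return self.n_pos == 0 or self.n_neg == 0

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""

    icc: float
    p_value: float
    n: int
    model: str = "two_way_random_single"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "model": self.model,
            "p_value": self.p_value,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def confusion_metrics(pred, truth, level: str = "custom") -> EvalReport:
    """Accuracy/sensitivity/specificity from two aligned boolean vectors."""
    pred = np.asarray(pred, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth lengths differ")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return EvalReport(level=level, tp=tp, tn=tn, fp=fp, fn=fn)


def volume_detection_label(bscan_area_pcts, min_area: float = 0.0) -> bool:
    """Volume positive iff any B-scan's area percentage exceeds min_area."""
    areas = np.asarray(list(bscan_area_pcts), dtype=float)
    return bool((areas > min_area).any()) if areas.size else False


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr, threshold) and its AUC.

    The AUC equals the Mann-Whitney probability that a random positive
    outranks a random negative, with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels lengths differ")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr, thr]), auc


def icc_agreement(x, y) -> ICCResult:
    """ICC(2,1) between two measurement methods over the same targets.

    Computed from the two-way ANOVA mean squares of the n x 2 table
    (targets x raters):

        ICC = (MSR - MSE) / (MSR + MSE + (2/n) * (MSC - MSE))

    with the F test MSR/MSE on (n-1, n-1) degrees of freedom for the
    significance of between-target consistency.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise ValidationError("icc_agreement requires n >= 3")
    data = np.column_stack([x, y])  # n targets x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / 1  # k - 1
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-15:
        return ICCResult(icc=float("nan"), p_value=float("nan"), n=n,
                         degenerate=True)
    icc = (msr - mse) / denom
    if mse <= 0:
        p = 0.0 if msr > 0 else float("nan")
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ICCResult(icc=float(icc), p_value=p, n=n)


def evaluate_run(
    pred_probs: dict[str, list[np.ndarray]],
    truth_masks: dict[str, list[np.ndarray]],
    threshold: float = 0.5,
    min_area: float = 0.0,
) -> dict:
    """Three-level evaluation of predicted probability maps against masks.

    ``pred_probs`` and ``truth_masks`` map a volume id to its per-B-scan
    probability maps and boolean ground-truth masks (same resolution).  A
    B-scan's truth label is any positive ground-truth pixel; its predicted
    label is positive area percentage above ``min_area``.  Volume labels
    aggregate B-scans.  Pixel-level metrics pool every pixel; the ROC
    sweeps the probability threshold over pooled pixels.  ICC compares
    per-B-scan area percentages between prediction and truth.
    """
    missing = set(truth_masks) ^ set(pred_probs)
    if missing:
        raise ValidationError(f"prediction/truth manifests differ: {sorted(missing)}")

    vol_pred, vol_truth = [], []
    bscan_pred, bscan_truth = [], []
    pred_area, truth_area = [], []
    pixel_scores, pixel_truth = [], []
    for vid in sorted(truth_masks):
        probs, masks = pred_probs[vid], truth_masks[vid]
        if len(probs) != len(masks):
            raise ValidationError(f"volume {vid}: B-scan counts differ")
        areas = []
        for prob, mask in zip(probs, masks):
            if prob.shape != mask.shape:
                raise ValidationError(f"volume {vid}: map shapes differ")
            scale = ScaleRecord(prob.shape, prob.shape)
            a_pred = measure_area_pct(prob, threshold, scale)
            a_true = 100.0 * np.count_nonzero(mask) / mask.size
            areas.append(a_pred)
            pred_area.append(a_pred)
            truth_area.append(a_true)
            bscan_pred.append(a_pred > min_area)
            bscan_truth.append(bool(mask.any()))
            pixel_scores.append(np.asarray(prob, dtype=float).ravel())
            pixel_truth.append(np.asarray(mask, dtype=bool).ravel())
        vol_pred.append(volume_detection_label(areas, min_area))
        vol_truth.append(any(bool(m.any()) for m in masks))

    scores = np.concatenate(pixel_scores)
    labels = np.concatenate(pixel_truth)
    pixel_report = confusion_metrics(scores >= threshold, labels, "pixel")
    curve, auc = roc_auc(scores, labels)
    pixel_report.auc = auc
    return {
        "volume": confusion_metrics(vol_pred, vol_truth, "volume"),
        "bscan": confusion_metrics(bscan_pred, bscan_truth, "bscan"),
        "pixel": pixel_report,
        "icc": icc_agreement(pred_area, truth_area),
        "roc_curve": curve,
        "pred_area_pct": np.asarray(pred_area),
        "truth_area_pct": np.asarray(truth_area),
    }
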