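"""Segmentation evaluation: confusion-matrix statistics, pixel ROC AUC,
and lesion-size-stratified reports.

Conventions for degenerate images: any metric whose denominator is zero
(e.g. precision with no predicted positives on an empty ground truth) is
defined as 1.0 — an all-negative prediction on an all-negative image is
vacuously correct. AUC is undefined for single-class images; those images
are skipped for AUC and counted in the report's exclusion tally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = ["MetricReport", "confusion_metrics", "auc_score", "evaluate",
           "STRATA"]

STRATA = ("all", "small", "large")


@dataclass
class MetricReport:
    """The six per-stratum statistics plus bookkeeping."""

    precision: float
    sensitivity: float
    specificity: float
    auc: float  # NaN when no image in the stratum had both classes
    iou: float
    dsc: float
    n_images: int
    stratum: str = "all"
    n_auc_excluded: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _check_binary(arr, name):
    arr = np.asarray(arr)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def _safe(num: float, den: float) -> float:
    return float(num) / float(den) if den > 0 else 1.0


def confusion_metrics(P_bin, B) -> dict[str, float]:
    """Precision, sensitivity, specificity, IoU and DSC from pixel counts."""
    P_bin = _check_binary(P_bin, "prediction")
    B = _check_binary(B, "mask")
    if P_bin.shape != B.shape:
        raise ValueError("prediction and mask shapes differ")
    tp = int(np.sum(P_bin & B))
    fp = int(np.sum(P_bin & ~B))
    fn = int(np.sum(~P_bin & B))
    tn = int(np.sum(~P_bin & ~B))
    return {
        "precision": _safe(tp, tp + fp),
        "sensitivity": _safe(tp, tp + fn),
        "specificity": _safe(tn, tn + fp),
        "iou": _safe(tp, tp + fp + fn),
        "dsc": _safe(2 * tp, 2 * tp + fp + fn),
    }


def dice(P_bin, B) -> float:
    return confusion_metrics(P_bin, B)["dsc"]


def auc_score(P_prob, B) -> float:
    """Pixel-score ROC AUC (the normalised Mann-Whitney statistic,
    midranks for ties). Returns NaN when the mask is single-class."""
    B = _check_binary(B, "mask").ravel()
    p = np.asarray(P_prob, dtype=np.float64).ravel()
    if p.shape != B.shape:
        raise ValueError("prediction and mask shapes differ")
    if B.all() or not B.any():
        return float("nan")
    return float(roc_auc_score(B.astype(np.int8), p))


def _aggregate(rows: list[dict], stratum: str) -> MetricReport:
    if not rows:
        return MetricReport(*[float("nan")] * 6, n_images=0, stratum=stratum)
    df = pd.DataFrame(rows)
    aucs = df["auc"].dropna()
    return MetricReport(
        precision=float(df["precision"].mean()),
        sensitivity=float(df["sensitivity"].mean()),
        specificity=float(df["specificity"].mean()),
        auc=float(aucs.mean()) if len(aucs) else float("nan"),
        iou=float(df["iou"].mean()),
        dsc=float(df["dsc"].mean()),
        n_images=len(df),
        stratum=stratum,
        n_auc_excluded=int(df["auc"].isna().sum()),
    )


def _pooled(counts: dict[str, float], aucs: list[float],
            n: int, n_excl: int, stratum: str) -> MetricReport:
    tp, fp, fn, tn = (counts[k] for k in ("tp", "fp", "fn", "tn"))
    return MetricReport(
        precision=_safe(tp, tp + fp),
        sensitivity=_safe(tp, tp + fn),
        specificity=_safe(tn, tn + fp),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        iou=_safe(tp, tp + fp + fn),
        dsc=_safe(2 * tp, 2 * tp + fp + fn),
        n_images=n, stratum=stratum, n_auc_excluded=n_excl,
    )


def evaluate(predict_fn, samples, threshold: float = 0.5,
             average: str = "macro") -> dict[str, MetricReport]:
    """Stratified evaluation of a probability-map predictor.

    Parameters
    ----------
    predict_fn:
        Callable mapping one image (H,W float array) to a probability map
        of the same spatial size.
    samples:
        Iterable of (image, mask, size_class) triples, where size_class is
        "small" or "large".
    threshold:
        Binarisation threshold in (0, 1).
    average:
        "macro" (per-image metrics averaged; the default) or "pooled"
        (confusion counts pooled over pixels; AUC stays per-image).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if average not in ("macro", "pooled"):
        raise ValueError("average must be 'macro' or 'pooled'")
    per_image: dict[str, list[dict]] = {s: [] for s in STRATA}
    pooled: dict[str, dict[str, float]] = {
        s: dict(tp=0, fp=0, fn=0, tn=0) for s in STRATA}
    pooled_aucs: dict[str, list[float]] = {s: [] for s in STRATA}

    for image, mask, size_class in samples:
        if size_class not in ("small", "large"):
            raise ValueError(f"unknown size class {size_class!r}")
        prob = np.asarray(predict_fn(image), dtype=np.float64)
        mask = _check_binary(mask, "mask")
        pred = prob > threshold
        row = confusion_metrics(pred.astype(np.uint8), mask.astype(np.uint8))
        row["auc"] = auc_score(prob, mask.astype(np.uint8))
        for s in ("all", size_class):
            per_image[s].append(row)
            pooled[s]["tp"] += int(np.sum(pred & mask))
            pooled[s]["fp"] += int(np.sum(pred & ~mask))
            pooled[s]["fn"] += int(np.sum(~pred & mask))
            pooled[s]["tn"] += int(np.sum(~pred & ~mask))
            if not np.isnan(row["auc"]):
                pooled_aucs[s].append(row["auc"])

    reports = {}
    for s in STRATA:
        if average == "macro":
            reports[s] = _aggregate(per_image[s], s)
        else:
            n = len(per_image[s])
            n_excl = sum(1 for r in per_image[s] if np.isnan(r["auc"]))
            reports[s] = _pooled(pooled[s], pooled_aucs[s], n, n_excl, s)
    return reports


def write_reports(reports: dict[str, MetricReport], json_path=None,
                  csv_path=None) -> None:
    """Serialise stratified reports as JSON and/or one-row-per-stratum CSV."""
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({s: r.as_dict() for s, r in reports.items()}, fh,
                      indent=2)
    if csv_path is not None:
        pd.DataFrame([r.as_dict() for r in reports.values()]).to_csv(
            csv_path, index=False)
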