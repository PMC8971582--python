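"""Precision / recall / F-measure evaluation of binary segmentation masks.

Conventions: the foreground ("target region") is label 1.  Precision is the
fraction of predicted foreground that is truly foreground, recall the fraction
of true foreground that was retrieved, and F the harmonic mean 2PR/(P+R).
Zero denominators yield 0 by convention.  Values are kept at full precision
internally; table display rounds to 4 decimals, half-up.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "precision",
    "recall",
    "f_measure",
    "evaluate_masks",
    "round_display",
    "write_metrics_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f_measure: float
    counts: ConfusionCounts | None = None


def _as_binary(mask, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype == bool:
        return m
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} mask must be binary (0/1), found values {vals[:5]}")
    return m.astype(bool)


def confusion(pred_mask, truth_mask) -> ConfusionCounts:
    """Pixel-wise confusion counts between a predicted and a true binary mask."""
    pred = _as_binary(pred_mask, "predicted")
    truth = _as_binary(truth_mask, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def f_measure(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if not (0.0 <= p <= 1.0) or not (0.0 <= r <= 1.0):
        raise ValueError(f"precision and recall must lie in [0, 1], got {p}, {r}")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def evaluate_masks(pred_mask, truth_mask) -> MetricsReport:
    """Full P/R/F report for a predicted mask against ground truth."""
    c = confusion(pred_mask, truth_mask)
    p = precision(c)
    r = recall(c)
    return MetricsReport(precision=p, recall=r, f_measure=f_measure(p, r), counts=c)


def round_display(x: float, ndigits: int = 4) -> float:
    """Round half-up to ``ndigits`` decimals, matching printed-table precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def write_metrics_csv(rows, path) -> None:
    """Write per-image metric rows (dicts with image_id, T, mu, P, R, F)."""
    fieldnames = ["image_id", "T", "mu", "P", "R", "F"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            out = dict(row)
            for key in ("P", "R", "F"):
                if key in out:
                    out[key] = f"{round_display(out[key]):.4f}"
            writer.writerow(out)
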