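"""Segmentation quality metrics.

Label maps are compared after majority-overlap matching: each predicted
segment is mapped to the ground-truth label it overlaps most.  Binary
metrics (accuracy, precision, F-measure, MCC, Jaccard, Dice, specificity)
are computed from one-vs-rest confusion counts and micro-averaged over the
ground-truth classes for multi-class maps.  The Probabilistic Rand Index
(PRI) scores pairwise same-segment/different-segment agreement, and SNR /
PSNR score the fidelity of the cluster-colour reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "match_labels",
    "confusion",
    "micro_confusion",
    "binary_metrics",
    "snr_psnr",
    "pri",
    "evaluate",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts over evaluated pixels."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    """The scalar quality metrics; fields are None until computed."""

    accuracy: float | None = None
    precision: float | None = None
    f_measure: float | None = None
    beta: float = 1.0
    mcc: float | None = None
    jaccard: float | None = None
    dice: float | None = None
    specificity: float | None = None
    snr_db: float | None = None
    psnr_db: float | None = None
    pri: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-safe dict; infinities become None with a flag already set."""
        out = {}
        for k in ("accuracy", "precision", "f_measure", "beta", "mcc", "jaccard",
                  "dice", "specificity", "snr_db", "psnr_db", "pri"):
            v = getattr(self, k)
            out[k] = None if v is not None and not math.isfinite(v) else v
        out["flags"] = list(self.flags)
        return out


def _contingency(pred: np.ndarray, gt: np.ndarray):
    pred = np.asarray(pred).ravel()
    gt = np.asarray(gt).ravel()
    pu, pi = np.unique(pred, return_inverse=True)
    gu, gi = np.unique(gt, return_inverse=True)
    table = np.zeros((len(pu), len(gu)), dtype=np.int64)
    np.add.at(table, (pi, gi), 1)
    return pu, gu, table


def match_labels(pred: np.ndarray, gt: np.ndarray) -> dict[int, int]:
    """Map each predicted label to the ground-truth label it overlaps most.

    Ties break toward the smaller ground-truth label.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    pu, gu, table = _contingency(pred, gt)
    # argmax returns the first (smallest) gt label on ties, gu being sorted
    best = np.argmax(table, axis=1)
    return {int(p): int(gu[b]) for p, b in zip(pu, best)}


def confusion(
    pred: np.ndarray, gt: np.ndarray, positive_class: int, matched: bool = False
) -> ConfusionCounts:
    """One-vs-rest confusion counts for one ground-truth class.

    Predicted labels are first mapped onto ground-truth labels by majority
    overlap (``match_labels``); pass ``matched=True`` when the prediction
    already uses the ground truth's label vocabulary.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if positive_class not in np.unique(gt):
        raise ValueError(f"positive_class {positive_class} not present in ground truth")
    if matched:
        mapped = pred
    else:
        mapping = match_labels(pred, gt)
        mapped = np.vectorize(mapping.__getitem__, otypes=[np.int64])(pred)
    p = mapped == positive_class
    g = gt == positive_class
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def micro_confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """One-vs-rest counts summed over every ground-truth class."""
    total = ConfusionCounts(0, 0, 0, 0)
    for cls in np.unique(gt):
        total = total + confusion(pred, gt, int(cls))
    return total


def binary_metrics(
    c: ConfusionCounts, beta: float = 1.0, paper_formulas: bool = False
) -> MetricsReport:
    """All confusion-based metrics from one set of counts.

    Conventions for empty denominators: MCC of 0/0 is 0; the others are 1
    when the positive class is both absent and never predicted (nothing was
    missed); each such case is flagged in the report.

    ``paper_formulas`` switches specificity to the nonstandard TN/(TN+FN)
    variant some sources print.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    r = MetricsReport(beta=beta)

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            r.flags.append(f"{name}: 0/0 -> 1 (class absent and unpredicted)")
            return 1.0
        return num / den

    r.accuracy = safe(tp + tn, tp + fn + fp + tn, "accuracy")
    r.precision = safe(tp, tp + fp, "precision")
    b2 = beta * beta
    r.f_measure = safe((b2 + 1) * tp, (b2 + 1) * tp + b2 * fn + fp, "f_measure")
    r.jaccard = safe(tp, tp + fn + fp, "jaccard")
    r.dice = safe(2 * tp, 2 * tp + fn + fp, "dice")
    if paper_formulas:
        r.specificity = safe(tn, tn + fn, "specificity")
    else:
        r.specificity = safe(tn, tn + fp, "specificity")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fn) * (tn + fp))
    if mcc_den == 0:
        r.flags.append("mcc: 0/0 -> 0")
        r.mcc = 0.0
    else:
        r.mcc = (tp * tn - fp * fn) / mcc_den
    return r


def snr_psnr(original: np.ndarray, reconstructed: np.ndarray) -> tuple[float, float]:
    """SNR and PSNR, in dB, of a reconstruction against the original.

    PSNR = 10 log10(255^2 / MSE); SNR = 10 log10(sum signal^2 / sum error^2),
    both over all channels.  Identical images give +inf for both.
    """
    orig = np.asarray(original, dtype=float)
    rec = np.asarray(reconstructed, dtype=float)
    if orig.shape != rec.shape:
        raise ValueError(f"shape mismatch: {orig.shape} vs {rec.shape}")
    err = orig - rec
    sse = float((err**2).sum())
    if sse == 0:
        return math.inf, math.inf
    mse = sse / err.size
    psnr = 10 * math.log10(255.0**2 / mse)
    sig = float((orig**2).sum())
    snr = math.inf if sig == 0 else 10 * math.log10(sig / sse)
    return snr, psnr


def _rand_index(pred: np.ndarray, gt: np.ndarray) -> float:
    _, _, table = _contingency(pred, gt)
    n = table.sum()
    if n < 2:
        return 1.0
    a = table.sum(axis=1)
    b = table.sum(axis=0)

    def c2(x):
        return float((x.astype(float) * (x - 1) / 2).sum())

    total = n * (n - 1) / 2
    same_both = c2(table.ravel())
    same_pred = c2(a)
    same_gt = c2(b)
    return (total - same_pred - same_gt + 2 * same_both) / total


def pri(pred: np.ndarray, gts: list[np.ndarray] | np.ndarray) -> float:
    """Probabilistic Rand Index of a segmentation against ground truth(s).

    For each ground truth, the fraction of unordered pixel pairs on which
    prediction and ground truth agree about same-label vs different-label
    membership, averaged over the ground truths; computed in
    O(N + labels^2) via the contingency-table identity, never by pair
    enumeration.
    """
    pred = np.asarray(pred)
    if isinstance(gts, np.ndarray) and gts.ndim == 2:
        gts = [gts]
    if len(gts) == 0:
        raise ValueError("need at least one ground truth")
    vals = []
    for gt in gts:
        gt = np.asarray(gt)
        if gt.shape != pred.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
        vals.append(_rand_index(pred, gt))
    return float(np.mean(vals))


def evaluate(
    pred: np.ndarray,
    gts: list[np.ndarray] | np.ndarray,
    original: np.ndarray | None = None,
    reconstructed: np.ndarray | None = None,
    beta: float = 1.0,
    paper_formulas: bool = False,
) -> MetricsReport:
    """Full report: micro-averaged confusion metrics + PRI (+ SNR/PSNR).

    Confusion metrics use the first ground truth; PRI averages over all of
    them.  SNR/PSNR are filled when both images are given.
    """
    if isinstance(gts, np.ndarray) and np.asarray(gts).ndim == 2:
        gts = [gts]
    report = binary_metrics(
        micro_confusion(pred, gts[0]), beta=beta, paper_formulas=paper_formulas
    )
    report.pri = pri(pred, gts)
    if original is not None and reconstructed is not None:
        report.snr_db, report.psnr_db = snr_psnr(original, reconstructed)
        if not math.isfinite(report.psnr_db):
            report.flags.append("snr_psnr: identical images -> infinite (null in JSON)")
    return report
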