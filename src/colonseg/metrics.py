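"""Segmentation evaluation: confusion counts, sensitivity/specificity/
accuracy, and the Dice coefficient.

Sensitivity = TP/(FN+TP), specificity = TN/(FP+TN), accuracy =
(TP+TN)/(FP+FN+TP+TN), DC = 2|A∩B|/(|A|+|B|); error is reported as
1 - accuracy.  Counts are computed at pixel granularity or at segment
granularity, where segments are 8-connected components matched by any
overlap.  At segment granularity true negatives need a population of
known non-target segments (e.g. ground-truth bowels and lungs); pass it
as ``negatives`` — without it TN is 0 and specificity is undefined.

A zero denominator raises :class:`UndefinedMetricError`; an undefined
metric is reported as not-applicable, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import as_bool

_EIGHT = np.ones((3, 3), dtype=int)


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    granularity: str = "pixel"

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    dice: float | None
    error: float | None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "dice": self.dice,
            "error": self.error,
        }

    def table(self) -> str:
        """Plain-text table of the metric values ('n/a' when undefined)."""
        rows = [
            ("Sensitivity (%)", self.sensitivity, 100.0),
            ("Specificity (%)", self.specificity, 100.0),
            ("Dice coefficient", self.dice, 1.0),
            ("Accuracy (%)", self.accuracy, 100.0),
            ("Error (%)", self.error, 100.0),
        ]
        width = max(len(r[0]) for r in rows)
        lines = []
        for name, value, scale in rows:
            shown = "n/a" if value is None else f"{value * scale:.2f}"
            lines.append(f"{name:<{width}}  {shown}")
        return "\n".join(lines)


def _stacks(pred, truth):
    p = [as_bool(m) for m in pred]
    t = [as_bool(m) for m in truth]
    if len(p) != len(t) or any(a.shape != b.shape for a, b in zip(p, t)):
        raise ValueError("prediction and truth stacks are misaligned")
    return p, t


def confusion(pred, truth, granularity: str = "pixel", negatives=None) -> ConfusionCounts:
    """Confusion counts between predicted and ground-truth mask stacks.

    ``pred`` and ``truth`` are sequences of 2-D masks (a single mask is
    accepted).  At segment granularity ``negatives`` supplies the stack of
    known non-target segments used for TN/FP accounting.
    """
    if isinstance(pred, np.ndarray) and pred.ndim == 2:
        pred, truth = [pred], [truth]
        if negatives is not None and np.asarray(negatives).ndim == 2:
            negatives = [negatives]
    p, t = _stacks(pred, truth)
    if granularity == "pixel":
        tp = fp = tn = fn = 0
        for a, b in zip(p, t):
            tp += int((a & b).sum())
            fp += int((a & ~b).sum())
            tn += int((~a & ~b).sum())
            fn += int((~a & b).sum())
        return ConfusionCounts(tp, fp, tn, fn, "pixel")
    if granularity != "segment":
        raise ValueError("granularity must be 'pixel' or 'segment'")

    neg = [as_bool(m) for m in negatives] if negatives is not None else [None] * len(p)
    tp = fp = tn = fn = 0
    for a, b, nm in zip(p, t, neg):
        tl, tn_segs = ndimage.label(b, structure=_EIGHT)
        for lb in range(1, tn_segs + 1):
            if (a & (tl == lb)).any():
                tp += 1
            else:
                fn += 1
        if nm is not None:
            nl, nn = ndimage.label(nm, structure=_EIGHT)
            for lb in range(1, nn + 1):
                if (a & (nl == lb)).any():
                    fp += 1
                else:
                    tn += 1
        else:
            pl, pn = ndimage.label(a, structure=_EIGHT)
            for lb in range(1, pn + 1):
                if not (b & (pl == lb)).any():
                    fp += 1
    return ConfusionCounts(tp, fp, tn, fn, "segment")


def sensitivity(c: ConfusionCounts) -> float:
    if c.FN + c.TP == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives")
    return c.TP / (c.FN + c.TP)


def specificity(c: ConfusionCounts) -> float:
    if c.FP + c.TN == 0:
        raise UndefinedMetricError("specificity undefined: no negatives")
    return c.TN / (c.FP + c.TN)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no units")
    return (c.TP + c.TN) / c.total


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); 1 means perfect overlap.

    Accepts single masks or stacks; both-empty input is undefined.
    """
    if not (isinstance(a, np.ndarray) and a.ndim == 2):
        a = np.concatenate([as_bool(m).ravel() for m in a])
        b = np.concatenate([as_bool(m).ravel() for m in b])
    a, b = as_bool(a), as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise UndefinedMetricError("dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def evaluate(pred, truth, granularity: str = "segment", negatives=None) -> MetricsReport:
    """Full metric report; Dice is always computed at pixel granularity."""
    c = confusion(pred, truth, granularity=granularity, negatives=negatives)

    def maybe(f, *args):
        try:
            return f(*args)
        except UndefinedMetricError:
            return None

    acc = maybe(accuracy, c)
    return MetricsReport(
        sensitivity=maybe(sensitivity, c),
        specificity=maybe(specificity, c),
        accuracy=acc,
        dice=maybe(dice, pred, truth),
        error=None if acc is None else 1.0 - acc,
    )
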