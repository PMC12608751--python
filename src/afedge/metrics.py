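"""Confusion-matrix accounting and the five derived window-level metrics.

Positive class is AF. From the four counts the report derives

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)            (recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)            (positive predictive value)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

A metric whose denominator is zero is reported as *undefined* (None) with
a warning, never silently coerced to 0 or 1. Percentages render with two
decimals, rounding half-up.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ValidationError

_METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN tallies; positive class = AF."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class MetricsReport:
    """The five derived metrics as fractions in [0, 1]; None = undefined."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None

    def as_percent(self, name: str) -> str:
        """Render one metric as a percentage with 2 decimals, half-up."""
        value = getattr(self, name)
        if value is None:
            return "undefined"
        pct = Decimal(repr(value * 100)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP)
        return f"{pct}%"

    def percent_values(self) -> dict[str, float | None]:
        """Numeric percentages rounded to 2 decimals (None if undefined)."""
        out: dict[str, float | None] = {}
        for name in _METRIC_NAMES:
            v = getattr(self, name)
            out[name] = None if v is None else float(
                Decimal(repr(v * 100)).quantize(Decimal("0.01"),
                                                rounding=ROUND_HALF_UP))
        return out

    def to_json(self) -> str:
        return json.dumps({n: getattr(self, n) for n in _METRIC_NAMES},
                          indent=2)

    def to_table(self) -> str:
        width = max(len(n) for n in _METRIC_NAMES)
        rows = [f"{n.ljust(width)}  {self.as_percent(n):>10}"
                for n in _METRIC_NAMES]
        return "\n".join(rows)


def confusion_from_pairs(truth, pred) -> ConfusionCounts:
    """Tally TP/FN/FP/TN from paired binary truth and prediction vectors."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValidationError(
            f"truth and pred must be equal-length 1-D vectors "
            f"(got {truth.shape} vs {pred.shape})")
    if not np.isin(truth, (0, 1)).all() or not np.isin(pred, (0, 1)).all():
        raise ValidationError("truth and pred must be strictly binary")
    truth = truth.astype(bool)
    pred = pred.astype(bool)
    return ConfusionCounts(
        tp=int((truth & pred).sum()),
        fn=int((truth & ~pred).sum()),
        fp=int((~truth & pred).sum()),
        tn=int((~truth & ~pred).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return None
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the five metrics from confusion counts (exact formulas)."""
    if c.total == 0:
        raise ValidationError("cannot compute metrics on zero counts")
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        if precision is not None and sensitivity is not None:
            warnings.warn("f1 undefined: precision + sensitivity is zero",
                          stacklevel=2)
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(accuracy, sensitivity, specificity, precision, f1)
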