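"""Binary diagnostic metrics from confusion counts.

Conventions: the *positive* label is the disease class (PD in the
DaTscan setting).  Metrics with a zero denominator are reported as
undefined (``None``) rather than silently coerced to 0, and render as
``"NA"``.  Percentages render with two decimals, rounding half up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Optional, Sequence

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metric_report", "counts_from_rates"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for one binary evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_label: Hashable = 1

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    y_true: Sequence[Hashable],
    y_pred: Sequence[Hashable],
    positive_label: Hashable = 1,
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for binary label sequences.

    Exactly two label values are allowed: ``positive_label`` and one
    other (the negative class).  A true positive is a positive sample
    predicted positive; a false positive is a negative sample predicted
    positive; and symmetrically for the negatives.
    """
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true labels vs {len(y_pred)} predictions"
        )
    labels = set(y_true) | set(y_pred)
    extra = labels - {positive_label}
    if len(extra) > 1:
        raise ValueError(
            f"binary evaluation expects two labels; found {sorted(map(repr, labels))} "
            f"with positive label {positive_label!r}"
        )
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn, positive_label)


def _percent(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    return str(Decimal(repr(x * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricReport:
    """Accuracy, precision, sensitivity, specificity and F1 on [0, 1];
    ``None`` marks an undefined (zero-denominator) metric."""

    accuracy: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]
    counts: Optional[ConfusionCounts] = None

    @property
    def rendered_percent(self) -> dict[str, str]:
        """Two-decimal round-half-up percent strings, ``"NA"`` if undefined."""
        return {
            "accuracy": _percent(self.accuracy),
            "precision": _percent(self.precision),
            "sensitivity": _percent(self.sensitivity),
            "specificity": _percent(self.specificity),
            "f1": _percent(self.f1),
        }

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "percent": self.rendered_percent,
        }
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            }
        return d


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metric_report(counts: ConfusionCounts) -> MetricReport:
    """Compute the five standard binary metrics from confusion counts.

    Accuracy = (TP+TN)/total, precision = TP/(TP+FP), sensitivity =
    TP/(TP+FN), specificity = TN/(FP+TN), F1 = harmonic mean of
    precision and sensitivity.  Any ratio with a zero denominator is
    undefined (``None``).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated samples")
    pr = _ratio(counts.tp, counts.tp + counts.fp)
    sn = _ratio(counts.tp, counts.tp + counts.fn)
    if pr is None or sn is None or pr + sn == 0:
        f1 = None
    else:
        f1 = 2 * pr * sn / (pr + sn)
    return MetricReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=pr,
        sensitivity=sn,
        specificity=_ratio(counts.tn, counts.fp + counts.tn),
        f1=f1,
        counts=counts,
    )


def counts_from_rates(
    sensitivity: float, specificity: float, n_positive: int, n_negative: int
) -> ConfusionCounts:
    """Recover integer confusion counts from printed sensitivity and
    specificity plus the class sizes, rounding to the nearest integer.

    Useful for cross-checking a published results table for internal
    consistency when only rates and class totals are reported.
    """
    tp = round(sensitivity * n_positive)
    tn = round(specificity * n_negative)
    if not (0 <= tp <= n_positive and 0 <= tn <= n_negative):
        raise ValueError("rates are inconsistent with the class sizes")
    return ConfusionCounts(tp=tp, tn=tn, fp=n_negative - tn, fn=n_positive - tp)
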