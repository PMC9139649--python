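"""Classical decision-level fusion rules: sum, product, majority vote.

These operate on the same :class:`~frlf.fusion_core.ScoreMatrix` as the
fuzzy-rank fusion and serve as comparison baselines.  All predictions
break ties toward the lowest class index; majority voting additionally
falls back to the sum rule over the tied classes before the index
tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion_core import InvalidScoreError, ScoreMatrix, is_normalized, normalize_scores

__all__ = ["BaselineResult", "sum_rule", "product_rule", "majority_vote", "fuse_with_rule"]


@dataclass(frozen=True)
class BaselineResult:
    """Combined per-class scores (or vote counts) and the argmax decision."""

    combined_scores: np.ndarray
    predicted_class: int
    rule_name: str
    class_ids: list[str]

    @property
    def predicted_class_id(self) -> str:
        return self.class_ids[self.predicted_class]


def _check(scores: ScoreMatrix, auto_normalize: bool) -> ScoreMatrix:
    if not is_normalized(scores):
        if auto_normalize:
            return normalize_scores(scores)
        raise InvalidScoreError(
            "score rows must sum to 1; normalize first or pass auto_normalize=True"
        )
    return scores


def sum_rule(scores: ScoreMatrix, auto_normalize: bool = False) -> BaselineResult:
    """Predict the class with the largest summed confidence over models."""
    scores = _check(scores, auto_normalize)
    combined = scores.scores.sum(axis=0)
    return BaselineResult(combined, int(np.argmax(combined)), "sum", list(scores.class_ids))


def product_rule(
    scores: ScoreMatrix, auto_normalize: bool = False, floor: float | None = None
) -> BaselineResult:
    """Predict the class with the largest product of confidences.

    A single zero annihilates a class.  ``floor``, when given, clips
    scores from below before multiplying; off by default since the plain
    rule uses the raw scores.
    """
    scores = _check(scores, auto_normalize)
    arr = scores.scores
    if floor is not None:
        if floor < 0:
            raise ValueError(f"floor must be >= 0, got {floor!r}")
        arr = np.maximum(arr, floor)
    combined = arr.prod(axis=0)
    return BaselineResult(combined, int(np.argmax(combined)), "product", list(scores.class_ids))


def majority_vote(scores: ScoreMatrix, auto_normalize: bool = False) -> BaselineResult:
    """Each model votes for its argmax class; the most-voted class wins.

    Vote ties cascade to the sum rule restricted to the tied classes,
    then to the lowest class index.
    """
    scores = _check(scores, auto_normalize)
    votes = np.argmax(scores.scores, axis=1)
    counts = np.bincount(votes, minlength=scores.n_classes)
    tied = np.flatnonzero(counts == counts.max())
    if len(tied) == 1:
        winner = int(tied[0])
    else:
        sums = scores.scores.sum(axis=0)[tied]
        winner = int(tied[np.argmax(sums)])  # argmax is first-max: lowest index
    return BaselineResult(counts.astype(float), winner, "majority", list(scores.class_ids))


def fuse_with_rule(scores: ScoreMatrix, rule: str, auto_normalize: bool = False) -> BaselineResult:
    """Dispatch by rule name: one of ``sum``, ``product``, ``majority``."""
    rules = {"sum": sum_rule, "product": product_rule, "majority": majority_vote}
    try:
        fn = rules[rule]
    except KeyError:
        raise ValueError(f"unknown rule {rule!r}; expected one of {sorted(rules)}") from None
    return fn(scores, auto_normalize=auto_normalize)
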