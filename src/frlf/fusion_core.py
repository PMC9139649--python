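"""Fuzzy rank level fusion (FRLF) of classifier confidence scores.

The method combines the per-class confidence scores of ``N`` base
classifiers into a single decision.  Each score ``CS`` in ``[0, 1]`` is
mapped to a *fuzzy rank*

    R(CS) = 1 - exp(-(CS - 1)^2 / (2 * variance)),

the complement of an (unnormalized) Gaussian centred at the ideal
confidence 1.  A perfect score gets rank 0; the rank grows toward
``1 - exp(-1/(2*variance))`` as the score falls to 0, so *smaller rank is
better*.  For every model the ``k`` best-ranked classes form its top-K
set.  A class accumulates, over models, its fuzzy rank (rank sum ``RS``)
and its confidence (complemented mean, ``CSS``); whenever the class
misses a model's top-K set, fixed penalties replace its rank and
confidence so that weakly supported classes are pushed away from the
decision.  The final score ``FS = RS * CSS`` is minimized over classes.

With the default hyper-parameters (k=1, rank penalty 0.33, confidence
penalty 0.05, variance 1.0) the decision rewards classes that are both
highly ranked by every model *and* backed by high raw confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScoreMatrix",
    "FuzzyRankMatrix",
    "FusionParams",
    "FusionResult",
    "InvalidScoreError",
    "normalize_scores",
    "is_normalized",
    "fuzzy_rank",
    "fuzzy_rank_matrix",
    "top_k_classes",
    "frlf_fuse",
    "frlf_fuse_batch",
]

#: Tolerance on row sums when deciding whether a score matrix is normalized.
NORMALIZATION_ATOL = 1e-6


class InvalidScoreError(ValueError):
    """Raised when a score matrix violates its invariants."""


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-sample grid of confidence scores, models along rows, classes
    along columns.

    Every entry must be finite and nonnegative.  Softmax outputs satisfy
    the row-sum-to-one constraint by construction; arbitrary scores can
    be brought to that form with :func:`normalize_scores`.
    """

    scores: np.ndarray
    model_ids: list[str] = field(default_factory=list)
    class_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2:
            raise InvalidScoreError(
                f"scores must be a 2-D model x class grid, got shape {arr.shape}"
            )
        n, c = arr.shape
        if n < 1 or c < 2:
            raise InvalidScoreError(
                f"need at least 1 model and 2 classes, got N={n}, C={c}"
            )
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            mid = self.model_ids[i] if self.model_ids else f"model{i}"
            cid = self.class_ids[j] if self.class_ids else f"class{j}"
            raise InvalidScoreError(
                f"score for model {mid!r}, class {cid!r} is invalid "
                f"({arr[i, j]!r}): entries must be finite and >= 0"
            )
        object.__setattr__(self, "scores", arr)
        if not self.model_ids:
            object.__setattr__(self, "model_ids", _default_ids("model", n))
        if not self.class_ids:
            object.__setattr__(self, "class_ids", _default_ids("class", c))
        if len(self.model_ids) != n or len(self.class_ids) != c:
            raise InvalidScoreError("id lists must match the score grid shape")

    @property
    def n_models(self) -> int:
        return self.scores.shape[0]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class FuzzyRankMatrix:
    """Elementwise fuzzy ranks sharing the index space of the source
    :class:`ScoreMatrix`.  Within a row, ranks order inversely to the
    source confidences: higher score, lower (better) rank."""

    ranks: np.ndarray
    model_ids: list[str]
    class_ids: list[str]


@dataclass(frozen=True)
class FusionParams:
    """FRLF hyper-parameters.

    k
        Size of each model's top-K set of best-ranked classes.
    rank_penalty
        Rank substituted for classes outside a model's top-K set.
    conf_penalty
        Confidence substituted for classes outside a model's top-K set.
    variance
        Variance of the Gaussian in the rank transform (the ``2 * 1.0``
        denominator); larger values flatten the ranking.
    """

    k: int = 1
    rank_penalty: float = 0.33
    conf_penalty: float = 0.05
    variance: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)) or self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k!r}")
        if self.variance <= 0 or not math.isfinite(self.variance):
            raise ValueError(f"variance must be > 0, got {self.variance!r}")
        for name in ("rank_penalty", "conf_penalty"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class FusionResult:
    """Per-class diagnostics and the argmin decision of one FRLF fusion."""

    rank_sums: np.ndarray
    conf_complements: np.ndarray
    final_scores: np.ndarray
    predicted_class: int
    top_k_sets: list[list[int]]
    class_ids: list[str]

    @property
    def predicted_class_id(self) -> str:
        return self.class_ids[self.predicted_class]


def normalize_scores(raw: ScoreMatrix) -> ScoreMatrix:
    """Scale each model row to sum to one, preserving proportions.

    An all-zero row carries no preference and maps to the uniform row
    ``1/C``.  Entry validation (finite, nonnegative) happens on
    :class:`ScoreMatrix` construction.
    """
    arr = raw.scores
    sums = arr.sum(axis=1, keepdims=True)
    c = raw.n_classes
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, arr / np.where(sums == 0, 1.0, sums), 1.0 / c)
    return ScoreMatrix(out, list(raw.model_ids), list(raw.class_ids))


def is_normalized(scores: ScoreMatrix, atol: float = NORMALIZATION_ATOL) -> bool:
    """True if every model row sums to one within ``atol``."""
    return bool(np.allclose(scores.scores.sum(axis=1), 1.0, atol=atol, rtol=0.0))


def fuzzy_rank(cs, variance: float = 1.0):
    """Gaussian-complement rank ``1 - exp(-(cs - 1)^2 / (2 * variance))``.

    Strictly decreasing in ``cs`` on [0, 1]; zero exactly at ``cs = 1``.
    Accepts scalars or arrays.
    """
    if variance <= 0:
        raise ValueError(f"variance must be > 0, got {variance!r}")
    cs = np.asarray(cs, dtype=float)
    out = 1.0 - np.exp(-((cs - 1.0) ** 2) / (2.0 * variance))
    return float(out) if out.ndim == 0 else out


def fuzzy_rank_matrix(scores: ScoreMatrix, params: FusionParams | None = None) -> FuzzyRankMatrix:
    """Apply :func:`fuzzy_rank` elementwise to a normalized score matrix."""
    params = params or FusionParams()
    return FuzzyRankMatrix(
        ranks=fuzzy_rank(scores.scores, params.variance),
        model_ids=list(scores.model_ids),
        class_ids=list(scores.class_ids),
    )


def top_k_classes(ranks: FuzzyRankMatrix, k: int) -> list[list[int]]:
    """Per model, the ``k`` classes with the smallest fuzzy rank.

    Ties are broken toward the lowest class index (stable sort), so the
    result is deterministic.
    """
    c = ranks.ranks.shape[1]
    if not 1 <= k <= c:
        raise ValueError(f"k must satisfy 1 <= k <= C={c}, got {k}")
    order = np.argsort(ranks.ranks, axis=1, kind="stable")
    return [list(map(int, row[:k])) for row in order]


def frlf_fuse(
    scores: ScoreMatrix,
    params: FusionParams | None = None,
    auto_normalize: bool = False,
) -> FusionResult:
    """Fuse one sample's model-by-class confidence scores with FRLF.

    For each class ``c``::

        RS_c  = sum_i ( R_c^i   if c in topK_i else rank_penalty )
        CSS_c = 1 - mean_i( CS_c^i if c in topK_i else conf_penalty )
        FS_c  = RS_c * CSS_c

    and the predicted class minimizes ``FS`` (lowest index on ties).

    Raises :class:`InvalidScoreError` if rows are not normalized, unless
    ``auto_normalize`` is set.
    """
    params = params or FusionParams()
    if not is_normalized(scores):
        if auto_normalize:
            scores = normalize_scores(scores)
        else:
            raise InvalidScoreError(
                "score rows must sum to 1; normalize first or pass auto_normalize=True"
            )
    n, c = scores.scores.shape
    if not params.k <= c:
        raise ValueError(f"k={params.k} exceeds number of classes C={c}")

    rank_mat = fuzzy_rank_matrix(scores, params)
    top_k = top_k_classes(rank_mat, params.k)

    member = np.zeros((n, c), dtype=bool)
    for i, classes in enumerate(top_k):
        member[i, classes] = True

    ranks = np.where(member, rank_mat.ranks, params.rank_penalty)
    confs = np.where(member, scores.scores, params.conf_penalty)

    rank_sums = ranks.sum(axis=0)
    conf_complements = 1.0 - confs.mean(axis=0)
    final_scores = rank_sums * conf_complements
    predicted = int(np.argmin(final_scores))  # argmin takes the first minimum

    return FusionResult(
        rank_sums=rank_sums,
        conf_complements=conf_complements,
        final_scores=final_scores,
        predicted_class=predicted,
        top_k_sets=top_k,
        class_ids=list(scores.class_ids),
    )


def frlf_fuse_batch(
    samples: Sequence[ScoreMatrix],
    params: FusionParams | None = None,
    auto_normalize: bool = False,
) -> list[FusionResult]:
    """Fuse a sequence of samples sharing the same N x C shape."""
    samples = list(samples)
    if not samples:
        return []
    shape = samples[0].scores.shape
    for s in samples[1:]:
        if s.scores.shape != shape:
            raise InvalidScoreError(
                f"heterogeneous sample shapes: {s.scores.shape} != {shape}"
            )
    return [frlf_fuse(s, params, auto_normalize=auto_normalize) for s in samples]
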