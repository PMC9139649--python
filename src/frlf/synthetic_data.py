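"""Synthetic confidence-score data emulating an ensemble of classifiers.

Generates labelled samples together with per-model softmax-style score
rows so that fusion rules and metrics can be exercised without any real
images or trained networks.  Each simulated model is correct (its
favored class equals the true label) independently with its configured
accuracy; the score row is drawn from a Dirichlet whose concentration
is loaded on the favored class, and the favored class is then swapped
into the argmax position so the configured accuracy is exact by
construction.  Larger ``concentration`` gives sharper, more confident
rows; in the limit rows become one-hot.

Defaults mirror the scale of the DaTscan test split this package
models: binary task with positive prevalence 86/129.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import baseline_fusion, fusion_core, metrics
from .fusion_core import FusionParams, ScoreMatrix

__all__ = ["SimulationConfig", "simulate_scores", "simulate_confusion_profile", "FUSION_RULES"]

FUSION_RULES = ("frlf", "sum", "product", "majority")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the score simulator.

    n_samples, n_models, n_classes
        Dataset and ensemble dimensions (binary by default).
    prevalence
        Fraction of samples whose true label is the positive class
        (class index 1 in the binary case).  Default 86/129, the
        positive fraction of the DaTscan test split.
    model_accuracies
        Per-model probability that the model favors the true class;
        defaults to 0.93 for every model.
    concentration
        Dirichlet mass on the favored class (others get 1); controls
        confidence sharpness.
    seed
        Seeds all draws; identical configs reproduce bitwise.
    """

    n_samples: int = 129
    n_models: int = 4
    n_classes: int = 2
    prevalence: float = 86 / 129
    model_accuracies: Sequence[float] = ()
    concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_models < 1 or self.n_classes < 2:
            raise ValueError("need n_samples >= 1, n_models >= 1, n_classes >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie strictly in (0, 1), got {self.prevalence}")
        if self.concentration <= 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        accs = tuple(self.model_accuracies) or (0.93,) * self.n_models
        if len(accs) != self.n_models:
            raise ValueError(
                f"model_accuracies has {len(accs)} entries for {self.n_models} models"
            )
        for a in accs:
            if not 0.5 < a <= 1.0:
                raise ValueError(f"model accuracy must lie in (0.5, 1], got {a}")
        object.__setattr__(self, "model_accuracies", accs)


def _draw_row(rng: np.random.Generator, favored: int, c: int, concentration: float) -> np.ndarray:
    alpha = np.ones(c)
    alpha[favored] = concentration
    row = rng.dirichlet(alpha)
    # Guarantee the favored class is the argmax: swap it with the current
    # argmax entry (preserves the row sum).
    top = int(np.argmax(row))
    if top != favored:
        row[favored], row[top] = row[top], row[favored]
    return row


def simulate_scores(cfg: SimulationConfig) -> tuple[np.ndarray, list[ScoreMatrix]]:
    """Draw true labels and one normalized ScoreMatrix per sample.

    Returns ``(labels, samples)`` where ``labels`` is an int array of
    true class indices (class 1 positive in the binary case) and each
    element of ``samples`` is the N x C score grid for one input.
    """
    rng = np.random.default_rng(cfg.seed)
    n, c = cfg.n_samples, cfg.n_classes
    if c == 2:
        labels = (rng.random(n) < cfg.prevalence).astype(int)
    else:
        labels = rng.integers(0, c, size=n)
    model_ids = [f"model{i}" for i in range(cfg.n_models)]
    class_ids = [f"class{j}" for j in range(c)]
    samples = []
    for s in range(n):
        rows = np.empty((cfg.n_models, c))
        for i, acc in enumerate(cfg.model_accuracies):
            if rng.random() < acc:
                favored = int(labels[s])
            else:  # model errs: favor a uniformly drawn wrong class
                wrong = [j for j in range(c) if j != labels[s]]
                favored = int(wrong[rng.integers(0, len(wrong))])
            rows[i] = _draw_row(rng, favored, c, cfg.concentration)
        samples.append(ScoreMatrix(rows, model_ids, class_ids))
    return labels, samples


def predict_with_rule(
    samples: Sequence[ScoreMatrix],
    rule: str,
    params: FusionParams | None = None,
) -> np.ndarray:
    """Per-sample class predictions under the named fusion rule."""
    if rule == "frlf":
        results = fusion_core.frlf_fuse_batch(samples, params)
        return np.array([r.predicted_class for r in results])
    if rule in ("sum", "product", "majority"):
        return np.array(
            [baseline_fusion.fuse_with_rule(s, rule).predicted_class for s in samples]
        )
    raise ValueError(f"unknown fusion rule {rule!r}; expected one of {FUSION_RULES}")


def simulate_confusion_profile(
    cfg: SimulationConfig,
    fusion_rule: str = "frlf",
    params: FusionParams | None = None,
    positive_class: int = 1,
) -> metrics.MetricReport:
    """Simulate scores, fuse with the named rule, and evaluate.

    Deterministic given the config seed.  Binary configs only (the
    metric suite is binary).
    """
    if cfg.n_classes != 2:
        raise ValueError("confusion profiles are defined for binary configs")
    labels, samples = simulate_scores(cfg)
    preds = predict_with_rule(samples, fusion_rule, params)
    counts = metrics.confusion(labels.tolist(), preds.tolist(), positive_label=positive_class)
    return metrics.metric_report(counts)
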