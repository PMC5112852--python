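"""Classifier evaluation metrics on class-belief matrices.

Four metrics over a beliefs matrix p_ik (sample i, class k; rows sum to 1)
against class indicators Y_ik:

* error rate   — fraction of samples whose argmax-belief class is wrong;
* GBS          — Generalized Brier Score, (1/2n) sum_ik (Y_ik - p_ik)^2,
                 0 perfect, 1 maximally wrong;
* BCM          — Belief Confusion Metric: the average belief assigned to a
                 sample's true class, macro-averaged over classes, 1 perfect;
* AUPR         — area under the precision-recall curve per class (average-
                 precision step convention), macro-averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PredictionSet:
    """Per-sample class beliefs with true class indices.

    ``beliefs`` is n x K with rows summing to 1; ``truth`` holds the true
    class index (column of ``beliefs``) per sample.
    """

    beliefs: np.ndarray
    truth: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        beliefs = np.asarray(self.beliefs, dtype=float)
        truth = np.asarray(self.truth, dtype=int)
        object.__setattr__(self, "beliefs", beliefs)
        object.__setattr__(self, "truth", truth)
        if beliefs.ndim != 2:
            raise ValueError("beliefs must be an n x K matrix")
        n, K = beliefs.shape
        if truth.shape != (n,):
            raise ValueError("truth must have one class index per sample")
        if len(self.class_names) != K:
            raise ValueError("class_names must have one entry per column")
        if n == 0:
            raise ValueError("empty prediction set")
        if (beliefs < 0).any() or (beliefs > 1).any():
            raise ValueError("beliefs must lie in [0, 1]")
        if np.abs(beliefs.sum(axis=1) - 1.0).max() > _ROW_SUM_TOL:
            raise ValueError("belief rows must sum to 1")
        if truth.min() < 0 or truth.max() >= K:
            raise ValueError("truth indices out of range")

    @classmethod
    def from_labels(cls, beliefs: np.ndarray, y: np.ndarray,
                    class_names: tuple[str, str] = ("diseased", "control")):
        """Build from a +1/-1 label vector; column 0 is the +1 class."""
        truth = np.where(np.asarray(y) == 1, 0, 1)
        return cls(beliefs=beliefs, truth=truth, class_names=tuple(class_names))

    @property
    def n(self) -> int:
        return self.beliefs.shape[0]

    @property
    def K(self) -> int:
        return self.beliefs.shape[1]

    @property
    def indicators(self) -> np.ndarray:
        Y = np.zeros_like(self.beliefs)
        Y[np.arange(self.n), self.truth] = 1.0
        return Y


def error_rate(pred: PredictionSet) -> float:
    """Misclassification fraction; class call is argmax belief (ties: first)."""
    calls = np.argmax(pred.beliefs, axis=1)
    return float((calls != pred.truth).mean())


def gbs(pred: PredictionSet) -> float:
    """Generalized Brier Score (1/2n) sum_ik (Y_ik - p_ik)^2."""
    resid = pred.indicators - pred.beliefs
    return float((resid**2).sum() / (2 * pred.n))


def bcm(pred: PredictionSet) -> float:
    """Mean true-class belief per class, macro-averaged over represented classes."""
    per_class = []
    for k in range(pred.K):
        mask = pred.truth == k
        if not mask.any():
            warnings.warn(f"class {pred.class_names[k]!r} has no samples; "
                          "omitted from BCM", stacklevel=2)
            continue
        per_class.append(float(pred.beliefs[mask, k].mean()))
    if not per_class:
        raise ValueError("no class has any samples")
    return float(np.mean(per_class))


def average_precision(beliefs_k: np.ndarray, positives: np.ndarray) -> float:
    """Average precision of one class's ranking (step-curve PR area).

    Samples are ranked by belief descending; ties keep the original sample
    order (stable sort) — tie-averaged orderings are not attempted.
    """
    if not positives.any():
        raise ValueError("average precision needs at least one positive")
    order = np.argsort(-np.asarray(beliefs_k, dtype=float), kind="stable")
    hits = np.asarray(positives, dtype=bool)[order]
    cum_hits = np.cumsum(hits)
    ranks = np.arange(1, hits.size + 1)
    precision_at_hit = cum_hits[hits] / ranks[hits]
    return float(precision_at_hit.sum() / hits.sum())


def aupr(pred: PredictionSet) -> float:
    """Macro-averaged per-class average precision.

    A class with zero positives is skipped with a warning; ties in the
    belief ranking are broken by sample order (warned, deterministic).
    """
    per_class = []
    for k in range(pred.K):
        positives = pred.truth == k
        if not positives.any():
            warnings.warn(f"class {pred.class_names[k]!r} has no positives; "
                          "skipped in AUPR", stacklevel=2)
            continue
        col = pred.beliefs[:, k]
        if np.unique(col).size < col.size:
            warnings.warn("tied beliefs broken by sample order in AUPR",
                          stacklevel=2)
        per_class.append(average_precision(col, positives))
    if not per_class:
        raise ValueError("every class was skipped: no positives anywhere")
    return float(np.mean(per_class))


def evaluate(pred: PredictionSet) -> dict[str, float]:
    """All four metrics as a dict (error as a fraction, not percent)."""
    return {"error": error_rate(pred), "gbs": gbs(pred),
            "bcm": bcm(pred), "aupr": aupr(pred)}
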