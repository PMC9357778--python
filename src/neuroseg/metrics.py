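"""Diagnostic-test metrics: confusion counts for diseased/non-diseased
groups and prevalence-weighted sensitivity, specificity, PPV, NPV and
accuracy, plus permutation-matched segmentation accuracy."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "prevalence_accuracy",
    "evaluate",
    "permutation_matched_accuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """M/N: test-positive/-negative among diseased; P/Q: among non-diseased."""

    M: int
    N: int
    P: int
    Q: int

    @property
    def total(self) -> int:
        return self.M + self.N + self.P + self.Q

    @property
    def prevalence(self) -> float:
        return (self.M + self.N) / self.total


def confusion_counts(predicted, truth) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth label lengths differ")
    for name, arr in (("predicted", predicted), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    diseased = truth == 1
    return ConfusionCounts(
        M=int(np.sum(diseased & (predicted == 1))),
        N=int(np.sum(diseased & (predicted == 0))),
        P=int(np.sum(~diseased & (predicted == 1))),
        Q=int(np.sum(~diseased & (predicted == 0))),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """M / (M + N): the fraction of diseased cases flagged positive."""
    if c.M + c.N < 1:
        raise ValueError("sensitivity undefined: no diseased cases")
    return c.M / (c.M + c.N)


def specificity(c: ConfusionCounts) -> float:
    """Q / (P + Q): the fraction of non-diseased cases flagged negative."""
    if c.P + c.Q < 1:
        raise ValueError("specificity undefined: no non-diseased cases")
    return c.Q / (c.P + c.Q)


def _check_rates(sens: float, spec: float, prevalence: float) -> None:
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")


def ppv(sens: float, spec: float, prevalence: float) -> float:
    """Probability of disease given a positive test."""
    _check_rates(sens, spec, prevalence)
    denom = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    if denom == 0.0:
        raise ValueError("PPV undefined: no positive tests possible")
    return sens * prevalence / denom


def npv(sens: float, spec: float, prevalence: float) -> float:
    """Probability of no disease given a negative test."""
    _check_rates(sens, spec, prevalence)
    denom = (1.0 - sens) * prevalence + spec * (1.0 - prevalence)
    if denom == 0.0:
        raise ValueError("NPV undefined: no negative tests possible")
    return spec * (1.0 - prevalence) / denom


def prevalence_accuracy(sens: float, spec: float, prevalence: float) -> float:
    """sens * prevalence + spec * (1 - prevalence); equals count-based
    accuracy when prevalence is the empirical one."""
    _check_rates(sens, spec, prevalence)
    return sens * prevalence + spec * (1.0 - prevalence)


def evaluate(predicted, truth, prevalence: float | None = None) -> dict:
    """Full report from label sequences; prevalence defaults to empirical."""
    c = confusion_counts(predicted, truth)
    sens = sensitivity(c)
    spec = specificity(c)
    pi = c.prevalence if prevalence is None else prevalence
    acc = prevalence_accuracy(sens, spec, pi)
    return {
        "M": c.M, "N": c.N, "P": c.P, "Q": c.Q,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv(sens, spec, pi),
        "npv": npv(sens, spec, pi),
        "prevalence": pi,
        "accuracy": acc,
        "accuracy_percent": 100.0 * acc,
    }


def permutation_matched_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Pixel accuracy under the best relabeling of predicted clusters.

    Cluster indices are arbitrary, so accuracy is taken as the maximum
    agreement over all assignments of predicted labels to truth labels.
    """
    labels = np.asarray(labels).ravel()
    truth = np.asarray(truth).ravel()
    if labels.shape != truth.shape:
        raise ValueError("label grids differ in size")
    pred_ids = np.unique(labels)
    true_ids = np.unique(truth)
    # contingency table, then best assignment by exhaustive permutation
    # (cluster counts are small)
    table = np.zeros((pred_ids.size, true_ids.size))
    for a, p in enumerate(pred_ids):
        for b, t in enumerate(true_ids):
            table[a, b] = np.sum((labels == p) & (truth == t))
    k = max(pred_ids.size, true_ids.size)
    best = 0.0
    for perm in permutations(range(k), pred_ids.size):
        score = sum(table[a, perm[a]] for a in range(pred_ids.size)
                    if perm[a] < true_ids.size)
        best = max(best, score)
    return best / labels.size
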