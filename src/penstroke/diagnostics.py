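"""ROC analysis of patient-level scores: AUC, Youden index, operating metrics.

The diagnostic read-out of the pipeline is patient-level: each subject's
likelihood-ratio score is thresholded to classify positive (affected) versus
negative, sweeping the threshold over midpoints between adjacent distinct
scores plus sentinels.  The Youden index J = max(sensitivity + specificity −
1) picks the optimal operating point ("associated criterion"); predictive
values and accuracy at that point use the study prevalence (the subject
counts of the comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import PatientScore


@dataclass(frozen=True)
class OperatingMetrics:
    """Prevalence-aware metrics at one (sensitivity, specificity) point.

    PPV/NPV are NaN when their denominator is zero (flagged undefined).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float


@dataclass
class ROCResult:
    """Full ROC curve with Youden-optimal operating point."""

    thresholds: np.ndarray  # ascending; rule: positive iff score > threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_j: float
    associated_criterion: float
    operating: OperatingMetrics
    n_pos: int
    n_neg: int


def operating_metrics(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> OperatingMetrics:
    """Closed-form PPV, NPV, accuracy and Youden J at given prevalence.

    accuracy = (sens·n_pos + spec·n_neg) / (n_pos + n_neg);
    PPV = sens·n_pos / (sens·n_pos + (1−spec)·n_neg);
    NPV = spec·n_neg / (spec·n_neg + (1−sens)·n_pos).
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sens and spec must be proportions in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    tp = sens * n_pos
    tn = spec * n_neg
    fp = (1 - spec) * n_neg
    fn = (1 - sens) * n_pos
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    accuracy = (tp + tn) / (n_pos + n_neg)
    return OperatingMetrics(sens, spec, ppv, npv, accuracy, sens + spec - 1)


def _coerce_scores(
    scores: Sequence[PatientScore] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    if len(scores) and isinstance(scores[0], PatientScore):
        scores = [s.lr for s in scores]
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC analysis needs both classes present")
    return s, y


def roc_curve(
    scores: Sequence[PatientScore] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
) -> ROCResult:
    """ROC curve over patient scores; larger scores mean more positive.

    Thresholds are the midpoints between adjacent distinct scores plus one
    sentinel below and above all scores; a case is called positive when its
    score exceeds the threshold.  AUC is the trapezoidal integral of the
    curve; Youden ties break toward the lower threshold (higher sensitivity).
    """
    s, y = _coerce_scores(scores, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    sens = np.array([(s[y == 1] > t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] <= t).mean() for t in thresholds])

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ascending fpr, then ascending tpr
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest threshold) tie
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_j=float(j[best]),
        associated_criterion=float(thresholds[best]),
        operating=operating_metrics(sens[best], spec[best], n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden(roc: ROCResult) -> tuple[float, float]:
    """(J, associated criterion): max sens + spec − 1, ties toward lower threshold."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = int(np.argmax(j))
    return float(j[best]), float(roc.thresholds[best])


def auc_rank_statistic(
    scores: Sequence[PatientScore] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
) -> float:
    """AUC as the Mann-Whitney rank statistic P(s⁺ > s⁻) + ½ P(s⁺ = s⁻).

    Exhaustive pairwise count; serves as the independent cross-check of the
    trapezoidal AUC.
    """
    s, y = _coerce_scores(scores, labels)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    n_pairs = pos.size * neg.size
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / n_pairs)
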