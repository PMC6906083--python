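"""Ranking and operating-point metrics.

AUROC is computed by the rank (Mann-Whitney concordance) definition: the
probability that a random case outscores a random control, ties counted 1/2.
The operating point fixes specificity: the threshold is the smallest score
cutoff whose empirical specificity reaches the target, and sensitivity is
reported there with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    if not np.all(pos | neg):
        raise ValueError("labels must be 0/1")
    return pos, neg


def auroc(scores, labels) -> float:
    """Pairwise-concordance AUROC (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    r = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class OperatingPoint:
    sensitivity: float
    specificity: float
    threshold: float
    attainable: bool = True


def sensitivity_at_specificity(scores, labels, spec_target: float = 0.98) -> OperatingPoint:
    """Maximum sensitivity subject to empirical specificity >= ``spec_target``.

    Classification rule: positive iff score >= threshold.  The threshold is
    the smallest candidate cutoff (an observed score, or +inf) meeting the
    constraint.  If no finite cutoff attains the target (e.g. all scores
    tied), sensitivity 0 at +inf is returned with ``attainable=False``.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    neg_scores = np.sort(scores[neg])
    n_neg = neg_scores.size
    for c in np.unique(scores):
        # specificity = fraction of controls strictly below the cutoff
        spec = np.searchsorted(neg_scores, c, side="left") / n_neg
        if spec >= spec_target:
            sens = float(np.mean(scores[pos] >= c))
            return OperatingPoint(sens, float(spec), float(c))
    return OperatingPoint(0.0, 1.0, np.inf, attainable=False)


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as (fpr, tpr) rows over all score cutoffs."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(labels)
    cuts = np.concatenate((np.unique(scores), [np.inf]))
    fpr = [(scores[neg] >= c).mean() for c in cuts]
    tpr = [(scores[pos] >= c).mean() for c in cuts]
    return np.column_stack((fpr, tpr))


def confusion_at(scores, labels, threshold: float) -> dict[str, int]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    return {"tp": int((pred & (labels == 1)).sum()),
            "fp": int((pred & (labels == 0)).sum()),
            "fn": int((~pred & (labels == 1)).sum()),
            "tn": int((~pred & (labels == 0)).sum())}
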