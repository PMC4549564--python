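"""Translate an in vitro signature to a xenograft cohort and quantify
discrimination by ROC/AUC.

The in vitro model predicts (standardized) log rIC50; the *sensitivity
score* of a xenograft is the negated prediction, so larger scores mean
predicted-sensitive. Outcomes are binarized to progression (PD1/PD2,
negative class) vs progression-free (SD/PR/CR/MCR, positive class): an AUC
above 0.5 then means predicted-sensitive tumors tend to respond. Because
training (cell lines) and validation (xenografts) are different cohorts and
platforms, xenograft expression is z-scored within the xenograft cohort.

AUC is computed as the tie-aware Mann-Whitney statistic
[#{s_pos > s_neg} + 0.5 #ties] / (n_pos n_neg), which equals the
trapezoidal area under the ROC curve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix
from .model import Signature, predict
from .response import ResponseClass, binarize_outcome

__all__ = [
    "RocResult",
    "score_xenografts",
    "binarize_cohort",
    "auc",
    "roc_curve",
    "auc_permutation_null",
]

POSITIVE_LABEL = "progression_free"
NEGATIVE_LABEL = "progression"


@dataclass
class RocResult:
    """ROC curve points, the AUC, and the class counts behind them."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = positive (progression-free)
    points: np.ndarray  # (n_thresholds+1, 2) of (fpr, tpr)
    auc: float
    n_pos: int
    n_neg: int


def score_xenografts(
    signature: Signature, xeno_expr: ExpressionMatrix
) -> np.ndarray:
    """Per-xenograft composite sensitivity score (larger = more sensitive).

    The xenograft cohort is z-scored per feature within itself; signature
    features missing from the platform contribute zero (at most 10% may be
    missing). Returns -predicted standardized log rIC50, aligned with
    ``xeno_expr.sample_ids``.
    """
    return -predict(signature, xeno_expr, standardize="cohort")


def binarize_cohort(classes: Sequence[ResponseClass]) -> np.ndarray:
    """Boolean labels, True where the class is progression-free."""
    if len(classes) == 0:
        raise ValueError("empty cohort")
    return np.array([binarize_outcome(c) == POSITIVE_LABEL for c in classes])


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(labels))
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC/AUC requires both outcome classes to be present "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    return n_pos, n_neg


def auc(scores, labels) -> float:
    """Tie-aware Mann-Whitney AUC: the probability a random positive
    outscores a random negative, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos, n_neg = _check_two_classes(labels)
    ranks = stats.rankdata(scores, method="average")
    rank_sum_pos = float(np.sum(ranks[labels]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve(scores, labels) -> RocResult:
    """ROC curve with thresholds at the unique score values (descending).

    Tied scores move the curve diagonally in one step, so the trapezoidal
    area equals ``auc`` exactly. Points start at (0,0) and end at (1,1),
    monotone in both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = _check_two_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    # keep only the last index of each tied block
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.append(distinct, len(s_sorted) - 1)
    tpr = np.concatenate([[0.0], tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp[idx] / n_neg])
    points = np.column_stack([fpr, tpr])
    area = float(np.trapezoid(tpr, fpr))
    return RocResult(
        scores=scores,
        labels=labels,
        points=points,
        auc=area,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_permutation_null(
    scores, labels, n_perm: int = 1000, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Label-permutation null for the AUC.

    Returns the null AUC sample and the one-sided add-one p-value for the
    observed AUC being as large or larger; the smallest attainable p is
    1/(n_perm+1). Under exchangeability the null has mean 0.5.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    observed = auc(scores, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = auc(scores, rng.permutation(labels))
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return null, p
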