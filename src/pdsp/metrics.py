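"""Regression and classification metrics for synergy evaluation.

Regression quality is measured by MSE and Pearson/Spearman correlation
between true and predicted Bliss scores.  Classification treats a pair as
synergistic when its (true or predicted) Bliss score is strictly positive —
no classifier is trained for this; the regression output is discretized.

Rank metrics (AUC, pAUC, AUPR) come from scikit-learn; ``roc_auc_score`` with
``max_fpr`` applies exactly the McClish standardization used for the partial
AUC here (random classifier maps to 0.5).  Thresholded metrics are computed
from confusion counts with explicit zero-division conventions, because
degenerate one-class predictors are a case this analysis must compare, not
crash on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .records import ValidationError

__all__ = [
    "ConfusionCounts",
    "regression_metrics",
    "confusion",
    "classification_metrics",
    "threshold_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    # zero-division conventions: an undefined ratio is reported as 0.0 so that
    # degenerate one-class predictors remain comparable
    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.recall + self.specificity)

    @property
    def kappa(self) -> float:
        """Cohen's kappa; 0 when chance agreement saturates (p_e == 1)."""
        n = self.total
        if n == 0:
            return 0.0
        p_o = (self.tp + self.tn) / n
        p_e = (
            (self.tp + self.fp) * (self.tp + self.fn)
            + (self.fn + self.tn) * (self.fp + self.tn)
        ) / (n * n)
        if p_e == 1.0:
            return 0.0
        return (p_o - p_e) / (1.0 - p_e)


def regression_metrics(y: Sequence[float], y_hat: Sequence[float]) -> dict[str, float]:
    """MSE plus Pearson and Spearman correlations (average ranks for ties).

    Correlations are undefined for constant vectors; that is an error rather
    than a silent zero.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 2:
        raise ValidationError("regression_metrics: need equal 1-D vectors, length >= 2")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return {
        "mse": float(np.mean((y - y_hat) ** 2)),
        "pearson": float(stats.pearsonr(y, y_hat).statistic),
        "spearman": float(stats.spearmanr(y, y_hat).statistic),
    }


def confusion(
    pred_labels: Sequence[int], true_labels: Sequence[int]
) -> ConfusionCounts:
    """Tabulate binary predictions against truth."""
    p = np.asarray(pred_labels)
    t = np.asarray(true_labels)
    if p.shape != t.shape or p.ndim != 1:
        raise ValidationError("confusion: need equal-length 1-D label vectors")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ValidationError("confusion: labels must be binary")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def _aupr_envelope(true_labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the step-wise precision envelope of the PR curve.

    The envelope interpolates precision at recall r as the maximum precision
    achieved at any recall >= r, then integrates stepwise over recall.
    """
    precision, recall, _ = precision_recall_curve(true_labels, scores)
    # precision_recall_curve returns recall decreasing to 0; reverse to
    # ascending recall and take the running maximum from the high-recall end.
    order = np.argsort(recall)
    r = recall[order]
    p = precision[order]
    env = np.maximum.accumulate(p)  # max precision at any recall >= r
    return float(np.sum(np.diff(r) * env[1:]))


def threshold_metrics(
    true_labels: Sequence[int], scores: Sequence[float], threshold: float = 0.0
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Discretize scores at the Bliss-class threshold and tabulate.

    A score strictly above the threshold is a synergistic (positive) call,
    matching the class definition used for the ground truth.
    """
    scores = np.asarray(scores, dtype=float)
    pred = (scores > threshold).astype(int)
    cm = confusion(pred, np.asarray(true_labels, dtype=int))
    return cm, {
        "f1": cm.f1,
        "precision": cm.precision,
        "recall": cm.recall,
        "kappa": cm.kappa,
        "bacc": cm.balanced_accuracy,
        "accuracy": cm.accuracy,
    }


def classification_metrics(
    true_labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.0,
    pauc_max_fpr: float = 0.1,
    standardize_pauc: bool = True,
) -> dict[str, float]:
    """All synergy-classification metrics from raw scores.

    Rank metrics need both classes in the truth and raise otherwise;
    thresholded metrics for single-class truth remain available through
    :func:`threshold_metrics`.  ``standardize_pauc=False`` reports the raw
    partial area (at most ``pauc_max_fpr``) instead of the McClish-scaled
    value.
    """
    t = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape or t.ndim != 1:
        raise ValidationError("classification_metrics: need equal 1-D vectors")
    if len(np.unique(t)) < 2:
        raise ValidationError(
            "rank metrics undefined: only one class present in the truth"
        )
    auc = float(roc_auc_score(t, s))
    pauc_std = float(roc_auc_score(t, s, max_fpr=pauc_max_fpr))
    if standardize_pauc:
        pauc = pauc_std
    else:
        # invert McClish to recover the raw partial area
        a_min = 0.5 * pauc_max_fpr**2
        a_max = pauc_max_fpr
        pauc = a_min + (pauc_std - 0.5) * 2.0 * (a_max - a_min)
    _, thr = threshold_metrics(t, s, threshold)
    return {
        "auc": auc,
        "pauc": pauc,
        "aupr": _aupr_envelope(t, s),
        **{k: thr[k] for k in ("f1", "precision", "recall", "kappa", "bacc")},
    }


def per_context_metrics(
    contexts: Sequence[str],
    y: Sequence[float],
    y_hat: Sequence[float],
) -> dict[str, dict[str, float]]:
    """Regression metrics broken down by context (cell line / patient)."""
    contexts = np.asarray(contexts)
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    out = {}
    for ctx in np.unique(contexts):
        sel = contexts == ctx
        try:
            out[str(ctx)] = regression_metrics(y[sel], y_hat[sel])
        except ValidationError:
            out[str(ctx)] = {"mse": float(np.mean((y[sel] - y_hat[sel]) ** 2))}
    return out
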