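"""Multi-label evaluation metrics and comparison arithmetic.

Five metrics summarize a multi-label prediction task: subset accuracy
(exact-match rate), macro-averaged F1, macro one-vs-rest AUC-ROC,
sample-averaged Jaccard index, and Hamming loss.  All are implemented
from their definitions on binary label matrices; scikit-learn serves
only as an independent cross-check in the test suite.

Conventions for degenerate denominators (all unit-tested):

* precision / recall / F1 are 0 when their denominator is 0;
* a sample whose truth and prediction are both empty has Jaccard 1;
* label columns containing a single class are excluded from macro AUC
  (an error is raised only if every column is excluded).

The Jaccard index here averages per-sample intersection-over-union over
samples; a per-label macro variant is exposed separately as
:func:`labelwise_jaccard`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "MetricsReport", "subset_accuracy", "hamming_loss", "macro_f1",
    "macro_auc", "macro_jaccard", "labelwise_jaccard", "evaluate_all",
    "relative_change", "absolute_drop", "UndefinedAUCError",
]


class UndefinedAUCError(ValueError):
    """No label column contains both a positive and a negative sample."""


def _as_binary(M, name: str) -> np.ndarray:
    M = np.asarray(M)
    if M.ndim != 2 or M.size == 0:
        raise ValueError(f"{name} must be a non-empty N x L matrix")
    if not np.isin(M, (0, 1)).all():
        raise ValueError(f"{name} entries must be 0 or 1")
    return M.astype(np.int64)


def _check_pair(Y, Yhat) -> tuple[np.ndarray, np.ndarray]:
    Y = _as_binary(Y, "Y")
    Yhat = _as_binary(Yhat, "Yhat")
    if Y.shape != Yhat.shape:
        raise ValueError("Y and Yhat must have the same shape")
    return Y, Yhat


def subset_accuracy(Y, Yhat) -> float:
    """Fraction of samples whose full label vector matches exactly."""
    Y, Yhat = _check_pair(Y, Yhat)
    return float((Y == Yhat).all(axis=1).mean())


def hamming_loss(Y, Yhat) -> float:
    """Fraction of the N*L individual label entries predicted wrongly."""
    Y, Yhat = _check_pair(Y, Yhat)
    return float((Y != Yhat).mean())


def _per_class_counts(Y: np.ndarray, Yhat: np.ndarray):
    tp = ((Y == 1) & (Yhat == 1)).sum(axis=0)
    fp = ((Y == 0) & (Yhat == 1)).sum(axis=0)
    fn = ((Y == 1) & (Yhat == 0)).sum(axis=0)
    return tp, fp, fn


def _safe_div(num, den) -> np.ndarray:
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    return np.divide(num, den, out=np.zeros_like(num, dtype=np.float64), where=den > 0)


def macro_f1(Y, Yhat, return_breakdown: bool = False):
    """Unweighted mean over classes of the per-class F1 score."""
    Y, Yhat = _check_pair(Y, Yhat)
    tp, fp, fn = _per_class_counts(Y, Yhat)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    value = float(f1.mean())
    if return_breakdown:
        return value, {"precision": precision, "recall": recall, "f1": f1}
    return value


def macro_auc(Y, S) -> float:
    """One-vs-rest AUC per label via the rank (Mann-Whitney) statistic.

    Ties are handled with midranks; single-class columns are skipped.
    """
    Y = _as_binary(Y, "Y")
    S = np.asarray(S, dtype=np.float64)
    if S.shape != Y.shape:
        raise ValueError("Y and S must have the same shape")
    if not np.isfinite(S).all():
        raise ValueError("scores must be finite")
    aucs = []
    for j in range(Y.shape[1]):
        y, s = Y[:, j], S[:, j]
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(s)  # midranks
        u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
        aucs.append(u / (n_pos * n_neg))
    if not aucs:
        raise UndefinedAUCError("every label column has a single class")
    return float(np.mean(aucs))


def macro_jaccard(Y, Yhat) -> float:
    """Per-sample intersection-over-union, averaged over samples.

    Samples where truth and prediction are both empty count as 1.
    """
    Y, Yhat = _check_pair(Y, Yhat)
    inter = ((Y == 1) & (Yhat == 1)).sum(axis=1)
    union = ((Y == 1) | (Yhat == 1)).sum(axis=1)
    per_sample = np.where(union > 0, _safe_div(inter, union), 1.0)
    return float(per_sample.mean())


def labelwise_jaccard(Y, Yhat) -> float:
    """Per-label intersection-over-union averaged over labels (the
    conventional macro form; provided for comparison with
    :func:`macro_jaccard`, which averages over samples)."""
    Y, Yhat = _check_pair(Y, Yhat)
    tp, fp, fn = _per_class_counts(Y, Yhat)
    union = tp + fp + fn
    per_label = np.where(union > 0, _safe_div(tp, union), 1.0)
    return float(per_label.mean())


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def relative_change(reference: float, new: float) -> float:
    """Percent change of ``new`` vs ``reference``: ``100 |new - ref| / ref``,
    rounded half-up to one decimal.  With the baseline as reference this is
    the improvement percentage; with the full model as reference it is the
    ablation/robustness decrease percentage."""
    if reference == 0:
        raise ZeroDivisionError("relative change undefined for zero reference")
    return _round1(100.0 * abs(new - reference) / reference)


def absolute_drop(standard: float, perturbed: float) -> float:
    """Point difference ``standard - perturbed`` on the printed percent
    scale, rounded half-up to one decimal."""
    return _round1(standard - perturbed)


REPORT_COLUMNS = (
    "Subset Accuracy(%)", "Macro F1(%)", "Macro AUC-ROC",
    "Jaccard Index(%)", "Hamming Loss(%)",
)


@dataclass
class MetricsReport:
    """The five metrics for one (truth, scores, predictions) triple."""

    subset_accuracy: float
    macro_f1: float
    macro_auc: float
    jaccard: float
    hamming_loss: float
    per_class: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("subset_accuracy", "macro_f1", "macro_auc",
                     "jaccard", "hamming_loss"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_fractions(self) -> dict[str, float]:
        return {"subset_accuracy": self.subset_accuracy, "macro_f1": self.macro_f1,
                "macro_auc": self.macro_auc, "jaccard": self.jaccard,
                "hamming_loss": self.hamming_loss}

    def as_percent_row(self) -> dict[str, float]:
        """Percent-scale values rounded to one decimal, report-table style."""
        vals = (self.subset_accuracy, self.macro_f1, self.macro_auc,
                self.jaccard, self.hamming_loss)
        return {col: _round1(100.0 * v) for col, v in zip(REPORT_COLUMNS, vals)}


def evaluate_all(Y, S, Yhat) -> MetricsReport:
    """All five metrics plus the per-class precision/recall/F1 breakdown."""
    f1, breakdown = macro_f1(Y, Yhat, return_breakdown=True)
    return MetricsReport(
        subset_accuracy=subset_accuracy(Y, Yhat),
        macro_f1=f1,
        macro_auc=macro_auc(Y, S),
        jaccard=macro_jaccard(Y, Yhat),
        hamming_loss=hamming_loss(Y, Yhat),
        per_class=breakdown,
    )
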