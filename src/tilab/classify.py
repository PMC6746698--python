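"""Binary TIL-positive/negative calls from co-localization scores.

A tissue section is called TIL-positive when its score meets or exceeds a
threshold.  Agreement with a pathologist's presence/absence labels is
summarised by accuracy, sensitivity, specificity, F1 and the ROC AUC
(Mann-Whitney statistic, ties counted 1/2) with a DeLong 95% confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from tilab.errors import ValidationError

__all__ = [
    "LabelledScore",
    "ClassifierMetrics",
    "classify_til_status",
    "confusion_metrics",
    "roc_auc",
]

TilStatus = Literal["TIL_POS", "TIL_NEG"]


@dataclass(frozen=True)
class LabelledScore:
    """One tissue section's score with the pathologist's TIL call."""

    unit_id: str
    score: float
    truth: TilStatus

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValidationError(f"score for {self.unit_id} is not finite")
        if self.truth not in ("TIL_POS", "TIL_NEG"):
            raise ValidationError(f"truth must be TIL_POS or TIL_NEG, got {self.truth!r}")


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion-table metrics plus AUC with 95% CI; all on the [0, 1] scale."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    f1: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    threshold: float | None = None


def classify_til_status(
    scores: Sequence[LabelledScore] | Sequence[float], threshold: float
) -> list[TilStatus]:
    """Threshold scores into TIL calls; score >= threshold is TIL-positive."""
    values = _score_values(scores)
    if values.size == 0:
        raise ValidationError("no scores to classify")
    return ["TIL_POS" if v >= threshold else "TIL_NEG" for v in values]


def _score_values(scores) -> np.ndarray:
    return np.asarray(
        [s.score if isinstance(s, LabelledScore) else float(s) for s in scores],
        dtype=float,
    )


def confusion_metrics(
    calls: Iterable[TilStatus],
    truth: Iterable[TilStatus],
    threshold: float | None = None,
) -> ClassifierMetrics:
    """Standard 2x2 confusion-table metrics with TIL_POS as the positive class.

    F1 is 0 when precision + recall is 0; with a single-class truth the
    undefined rate (sensitivity or specificity) is reported as None.
    """
    calls = list(calls)
    truth = list(truth)
    if len(calls) != len(truth) or not calls:
        raise ValidationError("calls and truth must be equal-length and non-empty")
    c = np.array([x == "TIL_POS" for x in calls])
    t = np.array([x == "TIL_POS" for x in truth])
    tp = int(np.sum(c & t))
    tn = int(np.sum(~c & ~t))
    fp = int(np.sum(c & ~t))
    fn = int(np.sum(~c & t))
    n_pos, n_neg = tp + fn, tn + fp
    accuracy = (tp + tn) / len(calls)
    sensitivity = tp / n_pos if n_pos else None
    specificity = tn / n_neg if n_neg else None
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = sensitivity or 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ClassifierMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        threshold=threshold,
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores: Sequence[LabelledScore], alpha: float = 0.05):
    """AUC with a DeLong confidence interval.

    The point estimate is the Mann-Whitney probability that a TIL-positive
    section outscores a TIL-negative one, ties counting 1/2; the variance is
    DeLong's structural-components estimator and the CI is normal on the AUC
    scale, truncated to [0, 1].

    Returns
    -------
    (auc, (ci_lower, ci_upper))
    """
    pos = np.array([s.score for s in scores if s.truth == "TIL_POS"], dtype=float)
    neg = np.array([s.score for s in scores if s.truth == "TIL_NEG"], dtype=float)
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValidationError("both TIL_POS and TIL_NEG sections are required for AUC")

    combined = np.concatenate([pos, neg])
    r_all = _midrank(combined)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    # DeLong structural components
    v10 = (r_all[:m] - r_pos) / n          # per positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # per negative
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))
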