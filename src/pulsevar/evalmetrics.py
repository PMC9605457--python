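"""Classification metrics: confusion counts with a reject option, operating
point AUC, rank AUC, likelihood ratio and adopted/excluded proportions.

Excluded decisions are dropped from the confusion counts but tallied, and
accuracy is computed over the adopted subjects only. The single operating
point AUC is the trapezoidal ROC area through one (1 - specificity,
sensitivity) point, i.e. (sensitivity + specificity) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sst

from .errors import EmptyReportError, InvalidParameterError, UndefinedAUCError
from .score import EXCLUDED, NEGATIVE, POSITIVE


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts (positives = label 1) plus excluded bookkeeping."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def n_adopted(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def cohort_size(self) -> int:
        return self.n_adopted + self.n_excluded

    @property
    def accuracy(self) -> float:
        """Percent correct among adopted subjects."""
        return 100.0 * (self.tp + self.tn) / self.n_adopted

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def auc(self) -> float:
        return binary_auc(self.sensitivity, self.specificity)

    @property
    def lr_plus(self) -> float:
        return likelihood_ratio_positive(self.sensitivity, self.specificity)

    @property
    def adopted_percent(self) -> float:
        return adopted_proportion(self)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_excluded": self.n_excluded,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "auc": self.auc,
            "lr_plus": self.lr_plus,
            "adopted_proportion": self.adopted_percent,
        }

    def render(self) -> str:
        lines = [
            "            pred-neg  pred-pos",
            f"label 0     {self.tn:8d}  {self.fp:8d}",
            f"label 1     {self.fn:8d}  {self.tp:8d}",
            f"excluded: {self.n_excluded}  "
            f"accuracy: {self.accuracy:.2f}%  "
            f"spec: {self.specificity:.2f}  sens: {self.sensitivity:.2f}  "
            f"AUC: {self.auc:.2f}",
        ]
        return "\n".join(lines)


def confusion(decisions: Sequence[str], labels: Sequence[int]) -> ClassificationReport:
    """Tally decisions against binary labels; excluded subjects are counted
    separately and do not enter the confusion matrix."""
    if len(decisions) != len(labels):
        raise InvalidParameterError(
            f"length mismatch: {len(decisions)} decisions vs {len(labels)} labels"
        )
    tp = fp = tn = fn = n_excluded = 0
    for d, y in zip(decisions, labels):
        y = int(y)
        if y not in (0, 1):
            raise InvalidParameterError(f"labels must be binary, got {y}")
        if d == EXCLUDED:
            n_excluded += 1
        elif d == POSITIVE:
            tp, fp = (tp + 1, fp) if y == 1 else (tp, fp + 1)
        elif d == NEGATIVE:
            tn, fn = (tn + 1, fn) if y == 0 else (tn, fn + 1)
        else:
            raise InvalidParameterError(f"unknown decision {d!r}")
    if tp + fp + tn + fn == 0:
        raise EmptyReportError("no adopted subjects")
    return ClassificationReport(tp=tp, fp=fp, tn=tn, fn=fn, n_excluded=n_excluded)


def binary_auc(sensitivity: float, specificity: float) -> float:
    """ROC area through a single operating point: (sens + spec) / 2."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
    return (sensitivity + specificity) / 2.0


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold-free AUC via the Mann-Whitney rank statistic (ties half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise InvalidParameterError("scores and labels must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("both classes must be present")
    ranks = sst.rankdata(s)
    u = float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def likelihood_ratio_positive(sensitivity: float, specificity: float) -> float:
    """LR+ = sensitivity / (1 - specificity); inf at specificity 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
    if specificity == 1.0:
        return math.inf
    return sensitivity / (1.0 - specificity)


def adopted_proportion(report: ClassificationReport) -> float:
    """Percent of the cohort outside the ambiguity band."""
    if report.cohort_size == 0:
        raise InvalidParameterError("empty cohort")
    return 100.0 * report.n_adopted / report.cohort_size
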