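"""Segmentation and diagnostic-accuracy evaluation.

Two layers:

* pixel level — :func:`jaccard_index`, the intersection-over-union of a
  predicted and a reference binary mask;
* case level — sensitivity / specificity / accuracy from a 2x2 confusion
  table against a pathology gold standard, and McNemar's paired chi-square
  test on the discordant calls of two modalities examined on the same
  cases.  The McNemar statistic with continuity correction is
  ``(|b - c| - 1)^2 / (b + c)`` with the numerator floored at zero;
  without correction it is ``(b - c)^2 / (b + c)``; p-values come from the
  chi-square distribution with one degree of freedom.

Metrics are proportions in [0, 1] throughout; format as percentages only
at the reporting edge.  A metric whose denominator is zero is reported as
explicitly undefined, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "ConfusionTable",
    "PairedCalls",
    "MetricReport",
    "jaccard_index",
    "diagnostic_metrics",
    "paired_chi_square",
    "confusion_from_calls",
    "cohort_report",
]

DEFAULT_ALPHA = 0.05


def jaccard_index(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on
    absence).  Symmetric in its arguments.
    """
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.shape != reference.shape:
        raise ValueError(
            f"mask geometry mismatch: {predicted.shape} vs {reference.shape}"
        )
    a = predicted.astype(bool)
    b = reference.astype(bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


@dataclass(frozen=True)
class ConfusionTable:
    """Case-level 2x2 diagnostic counts against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PairedCalls:
    """Per-case correctness of two modalities on the same cases.

    ``a`` = both correct, ``b`` = A correct / B wrong, ``c`` = A wrong /
    B correct, ``d`` = both wrong; ``a + b + c + d`` is the case count.
    """

    pairs: tuple[tuple[bool, bool], ...]

    @classmethod
    def from_arrays(cls, correct_a: Sequence[bool], correct_b: Sequence[bool]) -> "PairedCalls":
        correct_a = np.asarray(correct_a, dtype=bool)
        correct_b = np.asarray(correct_b, dtype=bool)
        if correct_a.shape != correct_b.shape:
            raise ValueError("paired call arrays must have equal length")
        return cls(tuple(zip(correct_a.tolist(), correct_b.tolist())))

    def _count(self, va: bool, vb: bool) -> int:
        return sum(1 for x, y in self.pairs if x == va and y == vb)

    @property
    def a(self) -> int:
        return self._count(True, True)

    @property
    def b(self) -> int:
        return self._count(True, False)

    @property
    def c(self) -> int:
        return self._count(False, True)

    @property
    def d(self) -> int:
        return self._count(False, False)


@dataclass(frozen=True)
class MetricReport:
    """Diagnostic metrics; ``None`` plus a reason where undefined."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    undefined: dict[str, str] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    statistic: float | None = None
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "undefined": dict(self.undefined),
            "alpha": self.alpha,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def diagnostic_metrics(table: ConfusionTable, alpha: float = DEFAULT_ALPHA) -> MetricReport:
    """Sensitivity, specificity and accuracy from a confusion table.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    accuracy = (tp+tn)/total.  A zero denominator yields an explicit
    undefined entry for that metric.
    """
    if table.total <= 0:
        raise ValueError("confusion table is empty")
    undefined: dict[str, str] = {}
    if table.tp + table.fn > 0:
        sensitivity = table.tp / (table.tp + table.fn)
    else:
        sensitivity = None
        undefined["sensitivity"] = "no diseased cases (tp + fn = 0)"
    if table.tn + table.fp > 0:
        specificity = table.tn / (table.tn + table.fp)
    else:
        specificity = None
        undefined["specificity"] = "no disease-free cases (tn + fp = 0)"
    accuracy = (table.tp + table.tn) / table.total
    return MetricReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        undefined=undefined,
        alpha=alpha,
    )


def paired_chi_square(
    calls: PairedCalls | tuple[int, int],
    continuity_correction: bool = True,
) -> tuple[float, float]:
    """McNemar's paired chi-square test on discordant calls.

    Accepts a :class:`PairedCalls` or a raw ``(b, c)`` discordance pair.
    With no discordant pairs the result is ``(0.0, 1.0)`` (nothing to
    test).  Returns ``(statistic, p_value)`` with the p-value from
    chi-square with 1 degree of freedom.
    """
    if isinstance(calls, PairedCalls):
        b, c = calls.b, calls.c
    else:
        b, c = calls
        if b < 0 or c < 0:
            raise ValueError("discordance counts must be nonnegative")
    if b + c == 0:
        return 0.0, 1.0
    if continuity_correction:
        numerator = max(abs(b - c) - 1, 0) ** 2
    else:
        numerator = (b - c) ** 2
    statistic = numerator / (b + c)
    return float(statistic), float(chi2.sf(statistic, df=1))


def confusion_from_calls(gold: Sequence[bool], correct: Sequence[bool]) -> ConfusionTable:
    """Confusion table from gold labels and per-case call correctness.

    A correct call on a diseased case is a true positive; a wrong call on
    a diseased case a false negative; and symmetrically for controls.
    """
    gold = np.asarray(gold, dtype=bool)
    correct = np.asarray(correct, dtype=bool)
    if gold.shape != correct.shape:
        raise ValueError("gold and correctness arrays must have equal length")
    return ConfusionTable(
        tp=int(np.count_nonzero(gold & correct)),
        fn=int(np.count_nonzero(gold & ~correct)),
        tn=int(np.count_nonzero(~gold & correct)),
        fp=int(np.count_nonzero(~gold & ~correct)),
    )


def cohort_report(
    gold: Sequence[bool],
    correct_a: Sequence[bool],
    correct_b: Sequence[bool],
    grades: Sequence[str | None],
    alpha: float = DEFAULT_ALPHA,
    continuity_correction: bool = True,
    labels: tuple[str, str] = ("modality_a", "modality_b"),
) -> dict:
    """Per-modality metrics and the paired test, overall and per grade.

    Returns a JSON-serializable dict with one block per modality
    (confusion table + metrics) and one paired-test block, for the whole
    cohort and for each grade stratum present.  Cases with missing grade
    labels are a contract error listing the offending case indices.
    """
    gold = np.asarray(gold, dtype=bool)
    correct_a = np.asarray(correct_a, dtype=bool)
    correct_b = np.asarray(correct_b, dtype=bool)
    if not (gold.shape == correct_a.shape == correct_b.shape):
        raise ValueError("gold and call arrays must have one entry per case")
    if len(grades) != gold.size:
        raise ValueError(f"expected {gold.size} grade labels, got {len(grades)}")
    missing = [i for i, g in enumerate(grades) if g is None or g == ""]
    if missing:
        raise ValueError(f"missing grade labels for case indices {missing}")
    grades = np.asarray(grades, dtype=object)

    def _stratum(mask: np.ndarray) -> dict:
        calls = PairedCalls.from_arrays(correct_a[mask], correct_b[mask])
        stat, p = paired_chi_square(calls, continuity_correction=continuity_correction)
        block: dict = {"n_cases": int(np.count_nonzero(mask))}
        for label, correct in ((labels[0], correct_a), (labels[1], correct_b)):
            table = confusion_from_calls(gold[mask], correct[mask])
            block[label] = {
                "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
                "metrics": diagnostic_metrics(table, alpha=alpha).to_dict(),
            }
        block["paired_test"] = {
            "b": calls.b,
            "c": calls.c,
            "statistic": stat,
            "p_value": p,
            "alpha": alpha,
            "significant": p < alpha,
            "continuity_correction": continuity_correction,
        }
        return block

    report = {"overall": _stratum(np.ones(gold.size, dtype=bool)), "by_grade": {}}
    seen: list[str] = []
    for g in grades:
        if g not in seen:
            seen.append(g)
    for g in seen:
        report["by_grade"][g] = _stratum(grades == g)
    return report
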