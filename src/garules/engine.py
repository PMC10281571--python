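"""Rule application and classifier performance metrics.

A conjunctive rule defines a single operating point of a binary
classifier: the rule's predicted class is the positive class, patients
satisfying every condition are predicted positive, the rest negative.
Patients missing any feature the rule references abstain and are
reported in ``excluded`` rather than entering the confusion counts.

Metrics follow the usual 2x2 definitions; the ROC AUC of a single
operating point is the two-point trapezoid ``(sensitivity +
specificity) / 2``.  Metrics whose denominator is zero are *undefined*
(``None``), never silently 0 or 1, so that degenerate rules (e.g. the
always-true rule) cannot masquerade as informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import FeatureMatrix
from .model import Comparator, CourseLabel, Rule

__all__ = [
    "ConfusionCounts",
    "RulePerformance",
    "apply_rule",
    "confusion",
    "performance",
    "evaluate_rule",
    "FeatureCache",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts plus the number of abstaining patients."""

    tp: int
    fn: int
    fp: int
    tn: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn, self.excluded) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        """T: number of positive-class patients entering the counts."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """F: number of negative-class patients entering the counts."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class RulePerformance:
    """Derived metrics of one rule; ``None`` marks an undefined metric."""

    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    kappa: Optional[float]
    roc_auc: Optional[float]

    def as_percent_dict(self, decimals: int = 2) -> dict:
        """Report-layer view: metrics as percentages rounded to
        ``decimals`` places, counts in the T/F convention."""
        c = self.counts

        def pct(x: Optional[float]):
            return None if x is None else round(100 * x, decimals)

        return {
            "TP": c.tp,
            "T": c.positives,
            "FP": c.fp,
            "F": c.negatives,
            "excluded": c.excluded,
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "accuracy": pct(self.accuracy),
            "PPV": pct(self.ppv),
            "NPV": pct(self.npv),
            "kappa": pct(self.kappa),
            "ROC AUC": pct(self.roc_auc),
        }


def performance(counts: ConfusionCounts) -> RulePerformance:
    """All 2x2 metrics from confusion counts, at full precision.

    Cohen's kappa is ``(Po - Pe) / (1 - Pe)`` with observed agreement
    ``Po`` equal to accuracy and chance agreement ``Pe`` computed from
    the marginal prediction/label frequencies.  Any metric whose
    denominator vanishes is ``None``.
    """
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    n = counts.total
    if n < 1:
        raise ValueError("confusion counts are all zero: nothing to evaluate")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, fp + tn)
    acc = (tp + tn) / n
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (acc - pe) / (1 - pe) if pe < 1 else None
    roc = (sens + spec) / 2 if sens is not None and spec is not None else None
    return RulePerformance(counts, sens, spec, acc, ppv, npv, kappa, roc)


Record = Union[Mapping[str, float], pd.Series]


def apply_rule(rule: Rule, record: Record) -> Optional[CourseLabel]:
    """Predict one patient's course, or abstain.

    Returns ``rule.predicted_class`` when every condition holds, the
    complementary class when any condition fails, and ``None``
    (abstain) when any referenced protein value is missing (NaN).

    Raises ``KeyError`` when a referenced protein is absent from the
    record's schema altogether — a schema error, distinct from a
    missing measurement.
    """
    all_hold = True
    for cond in rule.conditions:
        if cond.protein_id not in record:
            raise KeyError(f"protein {cond.protein_id!r} absent from patient record")
        value = record[cond.protein_id]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if not cond.holds(float(value)):
            all_hold = False
    return rule.predicted_class if all_hold else rule.predicted_class.complement


def _labels_array(
    labels: Union[Mapping[str, CourseLabel], pd.Series, Sequence[CourseLabel]],
    patient_ids: Sequence[str],
) -> np.ndarray:
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(labels, Mapping):
        missing = [p for p in patient_ids if p not in labels]
        if missing:
            raise ValueError(f"labels missing for patients: {missing}")
        seq = [labels[p] for p in patient_ids]
    else:
        seq = list(labels)
        if len(seq) != len(patient_ids):
            raise ValueError(
                f"label count {len(seq)} does not match patient count {len(patient_ids)}"
            )
    out = []
    for lab in seq:
        if isinstance(lab, str):
            lab = CourseLabel(lab)
        out.append(lab)
    return np.array([lab is CourseLabel.UNFAVOURABLE for lab in out])


class FeatureCache:
    """Vectorised condition evaluation against a fixed feature matrix.

    Caches the boolean satisfaction vector of each distinct condition,
    which makes repeated rule evaluation (the inner loop of the search)
    cheap.
    """

    def __init__(self, matrix: FeatureMatrix):
        self._matrix = matrix
        self._columns: dict[str, np.ndarray] = {}
        self._missing: dict[str, np.ndarray] = {}
        self._sat: dict[tuple, np.ndarray] = {}
        self.patient_ids = matrix.patient_ids
        self.n = len(self.patient_ids)

    def _col(self, pid: str) -> np.ndarray:
        if pid not in self._columns:
            col = self._matrix.column(pid)
            self._columns[pid] = col
            self._missing[pid] = ~np.isfinite(col)
        return self._columns[pid]

    def condition_sat(self, protein_id: str, comparator: Comparator, threshold: float) -> np.ndarray:
        key = (protein_id, comparator, threshold)
        if key not in self._sat:
            col = self._col(protein_id)
            with np.errstate(invalid="ignore"):
                sat = col <= threshold if comparator is Comparator.LE else col > threshold
            self._sat[key] = sat
        return self._sat[key]

    def rule_sat(self, rule: Rule) -> tuple[np.ndarray, np.ndarray]:
        """(satisfies, abstains) boolean vectors over patients."""
        sat = np.ones(self.n, dtype=bool)
        missing = np.zeros(self.n, dtype=bool)
        for cond in rule.conditions:
            sat &= self.condition_sat(cond.protein_id, cond.comparator, cond.threshold)
            missing |= self._missing[cond.protein_id]
        return sat & ~missing, missing


def confusion(
    rule: Rule,
    matrix: FeatureMatrix,
    labels: Union[Mapping[str, CourseLabel], pd.Series, Sequence[CourseLabel]],
    cache: FeatureCache | None = None,
) -> ConfusionCounts:
    """Confusion counts of a rule over a cohort.

    The positive class is ``rule.predicted_class``; patients with a
    missing value in any referenced feature are counted in ``excluded``.
    """
    cache = cache if cache is not None else FeatureCache(matrix)
    unfav = _labels_array(labels, cache.patient_ids)
    positive = unfav if rule.predicted_class is CourseLabel.UNFAVOURABLE else ~unfav
    sat, missing = cache.rule_sat(rule)
    keep = ~missing
    tp = int(np.sum(sat & positive & keep))
    fn = int(np.sum(~sat & positive & keep))
    fp = int(np.sum(sat & ~positive & keep))
    tn = int(np.sum(~sat & ~positive & keep))
    return ConfusionCounts(tp, fn, fp, tn, excluded=int(np.sum(missing)))


def evaluate_rule(
    rule: Rule,
    matrix: FeatureMatrix,
    labels,
    cache: FeatureCache | None = None,
) -> RulePerformance:
    """Convenience: confusion counts followed by metric derivation."""
    return performance(confusion(rule, matrix, labels, cache=cache))
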