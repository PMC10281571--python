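"""Domain types for prognostic rule mining on CSF proteomic data.

The central objects are conjunctive threshold rules over protein
fold-change features, and the dichotomised disease-course label derived
from the age-related MS severity (ARMSS) score: patients with ARMSS >= 5
at last follow-up form the unfavourable course group, those below 5 the
favourable group.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "CourseLabel",
    "Comparator",
    "Condition",
    "Rule",
    "PatientRecord",
    "RuleParseError",
    "course_label",
    "parse_rule_text",
    "serialize_rule",
    "LESION_SITES",
    "ONSET_SYMPTOMS",
]

#: Recognised lesion-localisation flags at disease onset.
LESION_SITES = frozenset(
    {"cerebral_high_load", "optic_nerve", "brainstem", "spinal_cord", "multifocal"}
)

#: Recognised symptom categories at disease onset.
ONSET_SYMPTOMS = frozenset(
    {
        "sensory",
        "motor",
        "gait",
        "optic_neuritis",
        "brainstem_other",
        "bladder_bowel",
        "lhermitte",
    }
)


class CourseLabel(enum.Enum):
    """Long-term disease course, dichotomised from the ARMSS score."""

    FAVOURABLE = "favourable"
    UNFAVOURABLE = "unfavourable"

    @property
    def complement(self) -> "CourseLabel":
        if self is CourseLabel.FAVOURABLE:
            return CourseLabel.UNFAVOURABLE
        return CourseLabel.FAVOURABLE

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CourseLabel.{self.name}"


def course_label(armss: float) -> CourseLabel:
    """Dichotomise an ARMSS score into a course label.

    Unfavourable iff ``armss >= 5`` (the boundary 5.0 is unfavourable),
    favourable otherwise.

    Parameters
    ----------
    armss:
        Age-related MS severity score on the 0-10 scale.

    Raises
    ------
    ValueError
        If ``armss`` is non-finite or outside [0, 10].
    """
    if not isinstance(armss, (int, float)) or isinstance(armss, bool):
        raise ValueError(f"ARMSS must be a real number, got {armss!r}")
    if not math.isfinite(armss):
        raise ValueError(f"ARMSS must be finite, got {armss!r}")
    if not 0.0 <= armss <= 10.0:
        raise ValueError(f"ARMSS must lie in [0, 10], got {armss}")
    return CourseLabel.UNFAVOURABLE if armss >= 5.0 else CourseLabel.FAVOURABLE


class Comparator(enum.Enum):
    """Threshold comparator of a rule condition.

    The rule dialect is normalised to the pair ``<=`` / ``>``: together
    they tile the real line, so a conjunction of them expresses any
    axis-aligned box over the features.
    """

    LE = "<="
    GT = ">"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Comparator.{self.name}"


@dataclass(frozen=True)
class Condition:
    """A single threshold predicate on one protein's fold-change value."""

    protein_id: str
    comparator: Comparator
    threshold: float

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("Condition protein_id must be non-empty")
        if not math.isfinite(self.threshold):
            raise ValueError(f"Condition threshold must be finite, got {self.threshold}")

    def holds(self, value: float) -> bool:
        """Evaluate the predicate on a single feature value."""
        if self.comparator is Comparator.LE:
            return value <= self.threshold
        return value > self.threshold

    def __str__(self) -> str:
        return f"{self.protein_id}{self.comparator.value}{_fmt(self.threshold)}"


def _fmt(x: float) -> str:
    """Format a threshold the way the rule dialect prints it (1.0, 2.5)."""
    if float(x) == int(x):
        return f"{x:.1f}"
    return f"{x:g}"


def _check_consistency(conditions: Sequence[Condition]) -> None:
    """Reject conjunctions whose satisfiable set is provably empty.

    For each protein, the conjunction restricts the value to
    ``(max gt-threshold, min le-threshold]``; the interval is empty when
    the tightest ``>`` bound is at or above the tightest ``<=`` bound.
    """
    lo: dict[str, float] = {}  # tightest strict lower bound per protein
    hi: dict[str, float] = {}  # tightest upper bound per protein
    for cond in conditions:
        p = cond.protein_id
        if cond.comparator is Comparator.GT:
            lo[p] = max(lo.get(p, -math.inf), cond.threshold)
        else:
            hi[p] = min(hi.get(p, math.inf), cond.threshold)
    for p in lo:
        if p in hi and lo[p] >= hi[p]:
            raise ValueError(
                f"Contradictory conditions on {p!r}: requires value > {lo[p]} "
                f"and value <= {hi[p]}"
            )


@dataclass(frozen=True)
class Rule:
    """A conjunction of threshold predicates predicting one course class.

    A patient satisfying every condition is predicted as
    ``predicted_class``; a patient failing any condition is predicted as
    the complementary class. Construction rejects empty conjunctions and
    conjunctions that no feature vector can satisfy.
    """

    conditions: tuple[Condition, ...]
    predicted_class: CourseLabel

    def __init__(self, conditions: Iterable[Condition], predicted_class: CourseLabel):
        conds = tuple(conditions)
        if not conds:
            raise ValueError("Rule must have at least one condition")
        _check_consistency(conds)
        object.__setattr__(self, "conditions", conds)
        object.__setattr__(self, "predicted_class", predicted_class)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(c.protein_id for c in self.conditions)

    def canonical_key(self) -> tuple:
        """Hashable identity ignoring condition order (for deduplication)."""
        return (
            self.predicted_class.value,
            tuple(sorted((c.protein_id, c.comparator.value, c.threshold) for c in self.conditions)),
        )

    def __str__(self) -> str:
        return serialize_rule(self)


@dataclass
class PatientRecord:
    """Clinical covariates for one patient of the prospective cohort."""

    patient_id: str
    age: float
    sex: str
    follow_up: float
    edss_tap: float
    edss_last: float
    armss: float
    ocb_positive: Optional[bool] = None
    igg_index: Optional[float] = None
    lesion_flags: frozenset[str] = field(default_factory=frozenset)
    symptom_flags: frozenset[str] = field(default_factory=frozenset)
    dmt_initiated: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.follow_up < 0:
            raise ValueError(f"follow_up must be >= 0, got {self.follow_up}")
        for name in ("edss_tap", "edss_last"):
            v = getattr(self, name)
            if not (0.0 <= v <= 10.0) or (2 * v) != int(2 * v):
                raise ValueError(f"{name} must be in 0..10 in 0.5 steps, got {v}")
        course_label(self.armss)  # validates range
        self.lesion_flags = frozenset(self.lesion_flags)
        self.symptom_flags = frozenset(self.symptom_flags)
        if not self.lesion_flags <= LESION_SITES:
            raise ValueError(f"unknown lesion flags: {sorted(self.lesion_flags - LESION_SITES)}")
        if not self.symptom_flags <= ONSET_SYMPTOMS:
            raise ValueError(f"unknown symptom flags: {sorted(self.symptom_flags - ONSET_SYMPTOMS)}")

    @property
    def course(self) -> CourseLabel:
        return course_label(self.armss)


# ---------------------------------------------------------------------------
# Rule text dialect
#
#   ARMSS>=5.0 IF { CD36<=1.0 AND A2M>2.5 AND ApoA1<=1.0 }
#
# The class header names the predicted group: `ARMSS>=X` predicts the
# unfavourable course, `ARMSS<X` the favourable course.  Typeset variants
# with split comparators (`< =`), stray italics asterisks and arbitrary
# whitespace are accepted on input; serialisation always emits the
# canonical form above.
# ---------------------------------------------------------------------------


class RuleParseError(ValueError):
    """Raised for malformed rule text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_IDENT = r"[A-Za-z_][A-Za-z0-9_.\-]*"

_HEADER_RE = re.compile(rf"\s*ARMSS\s*(>=|<)\s*({_NUM})\s*IF\s*\{{", re.IGNORECASE)
_COND_RE = re.compile(rf"\s*({_IDENT})\s*(<=|>)\s*({_NUM})\s*")


def _normalise(text: str) -> str:
    # drop typographic italics markers and unify split comparators
    t = text.replace("*", "")
    t = re.sub(r"<\s*=", "<=", t)
    t = re.sub(r">\s*=", ">=", t)
    return t


def parse_rule_text(text: str) -> Rule:
    """Parse a rule from the ``IF { ... }`` text dialect.

    Examples
    --------
    >>> r = parse_rule_text("ARMSS<5.0 IF { CD36<=1.0 AND A2M>2.5 AND ApoA1<=1.0 }")
    >>> r.predicted_class
    CourseLabel.FAVOURABLE
    >>> len(r.conditions)
    3
    """
    t = _normalise(text)
    m = _HEADER_RE.match(t)
    if m is None:
        raise RuleParseError(
            "expected class header 'ARMSS>=X IF {' or 'ARMSS<X IF {'", 0
        )
    predicted = CourseLabel.UNFAVOURABLE if m.group(1) == ">=" else CourseLabel.FAVOURABLE
    pos = m.end()
    close = t.find("}", pos)
    if close < 0:
        raise RuleParseError("missing closing '}'", len(t))
    body = t[pos:close]
    if not body.strip():
        raise RuleParseError("empty rule body: at least one condition required", pos)
    conditions: list[Condition] = []
    # split on AND at the top level (case-insensitive, whole word)
    parts = re.split(r"\bAND\b", body, flags=re.IGNORECASE)
    offset = pos
    for part in parts:
        cm = _COND_RE.fullmatch(part)
        if cm is None:
            raise RuleParseError(
                f"malformed condition {part.strip()!r}: expected '<protein><=|><number>'",
                offset,
            )
        comparator = Comparator.LE if cm.group(2) == "<=" else Comparator.GT
        conditions.append(Condition(cm.group(1), comparator, float(cm.group(3))))
        offset += len(part) + 3  # best-effort position tracking past 'AND'
    tail = t[close + 1 :].strip()
    if tail:
        raise RuleParseError(f"unexpected trailing text {tail!r}", close + 1)
    try:
        return Rule(conditions, predicted)
    except ValueError as exc:
        raise RuleParseError(str(exc), pos) from exc


def serialize_rule(rule: Rule) -> str:
    """Render a rule in the canonical text dialect."""
    header = "ARMSS>=5.0" if rule.predicted_class is CourseLabel.UNFAVOURABLE else "ARMSS<5.0"
    body = " AND ".join(str(c) for c in rule.conditions)
    return f"{header} IF {{ {body} }}"
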