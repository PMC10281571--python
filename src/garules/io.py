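"""Readers and writers for cohort tables, feature matrices and rule files.

All tabular I/O is CSV/TSV with UTF-8 encoding and a ``.`` decimal
point.  Feature matrices are patients x proteins on the fold-change
scale; missing cells stay missing (NaN) and are never silently zeroed.
Round-trips are lossless at 15 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .model import Comparator, Condition, CourseLabel, Rule, course_label

__all__ = [
    "FeatureMatrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_cohort",
    "write_cohort",
    "read_rules_json",
    "write_rules_json",
    "rules_to_json",
    "rules_from_json",
]

PathLike = Union[str, Path]

#: Columns a cohort table must provide.  ``armss`` drives the course label.
COHORT_REQUIRED = ("patient_id", "armss")


def _sep_for(path: PathLike, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
        return "," if dialect == "csv" else "\t"
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


@dataclass(frozen=True)
class FeatureMatrix:
    """Continuous protein fold-change values, one row per patient.

    Wraps a pandas DataFrame whose index holds patient ids and whose
    columns hold protein ids; both must be unique.  NaN marks a missing
    measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric feature columns: {non_numeric}")

    @property
    def patient_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def protein_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, protein_id: str) -> np.ndarray:
        if protein_id not in self.values.columns:
            raise KeyError(f"protein {protein_id!r} not in feature matrix")
        return self.values[protein_id].to_numpy(dtype=float)

    def row(self, patient_id: str) -> pd.Series:
        return self.values.loc[patient_id]


def read_feature_matrix(path: PathLike, dialect: str | None = None) -> FeatureMatrix:
    """Read a patients-x-proteins table (first column = patient ids).

    Raises ``ValueError`` naming the offending row/column on duplicate
    ids, ragged rows or non-numeric cells; empty cells are read as
    missing.
    """
    sep = _sep_for(path, dialect)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    dup_cols = sorted({c for c in header if header.count(c) > 1})
    if dup_cols:
        raise ValueError(f"duplicate protein columns: {dup_cols}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.index.name is None:
        df.index.name = "patient_id"
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = {}
    for col in df.columns:
        raw = df[col]
        cells = raw.replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})
        try:
            out[col] = cells.astype(float)
        except ValueError:
            bad = next(
                (pid, v)
                for pid, v in cells.items()
                if isinstance(v, str)
                and not _is_number(v)
            )
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {bad[0]!r}: {bad[1]!r}"
            ) from None
    return FeatureMatrix(pd.DataFrame(out, index=df.index))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_feature_matrix(matrix: FeatureMatrix, path: PathLike, dialect: str | None = None) -> None:
    """Write a feature matrix; missing values become empty cells."""
    sep = _sep_for(path, dialect)
    matrix.values.to_csv(path, sep=sep, float_format="%.17g", na_rep="")


def read_cohort(path: PathLike, dialect: str | None = None) -> pd.DataFrame:
    """Read a clinical cohort table and derive the course label.

    Requires ``patient_id`` and ``armss`` columns; returns the table
    indexed by patient id with an added ``course`` column holding
    ``favourable`` / ``unfavourable`` per the ARMSS >= 5 dichotomy.
    """
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids in cohort table: {dups}")
    df = df.set_index(df["patient_id"].astype(str)).drop(columns=["patient_id"])
    df.index.name = "patient_id"
    df["course"] = [course_label(a).value for a in df["armss"].astype(float)]
    return df


def write_cohort(cohort: pd.DataFrame, path: PathLike, dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    cohort.to_csv(path, sep=sep, float_format="%.17g", index_label="patient_id")


def cohort_labels(cohort: pd.DataFrame) -> pd.Series:
    """Course labels (CourseLabel) indexed by patient id."""
    return cohort["course"].map(CourseLabel)


# ---------------------------------------------------------------------------
# Rule JSON: [{"predicted_class": "...", "conditions": [{"protein": ...,
# "comparator": "le"|"gt", "threshold": ...}, ...]}, ...]
# ---------------------------------------------------------------------------

_COMPARATOR_NAMES = {"le": Comparator.LE, "gt": Comparator.GT}


def rules_to_json(rules: Sequence[Rule]) -> list[dict]:
    return [
        {
            "predicted_class": r.predicted_class.value,
            "conditions": [
                {
                    "protein": c.protein_id,
                    "comparator": "le" if c.comparator is Comparator.LE else "gt",
                    "threshold": c.threshold,
                }
                for c in r.conditions
            ],
        }
        for r in rules
    ]


def rules_from_json(payload: Sequence[Mapping]) -> list[Rule]:
    rules = []
    for i, entry in enumerate(payload):
        try:
            cls = CourseLabel(entry["predicted_class"])
            conds = [
                Condition(c["protein"], _COMPARATOR_NAMES[c["comparator"]], float(c["threshold"]))
                for c in entry["conditions"]
            ]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed rule entry {i}: {exc}") from exc
        rules.append(Rule(conds, cls))
    return rules


def write_rules_json(rules: Sequence[Rule], path: PathLike) -> None:
    Path(path).write_text(json.dumps(rules_to_json(rules), indent=2) + "\n", encoding="utf-8")


def read_rules_json(path: PathLike) -> list[Rule]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, list):
        raise ValueError("rules JSON must be a list of rule objects")
    return rules_from_json(payload)
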