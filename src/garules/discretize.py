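"""Equal-frequency discretisation of continuous protein features.

Continuous fold-change values are converted into ``k`` ordered
categories either by equal-frequency binning (as many samples per
category as ties permit) or by user-supplied cut-offs.  The resulting
cutpoints double as the threshold vocabulary available to the rule
search: every candidate condition threshold is one of these cutpoints.

Conventions
-----------
* A value equal to a cutpoint falls in the lower bin, matching the
  ``<=`` predicate family of the rule dialect.
* A cutpoint never separates equal values; under heavy ties, occupancy
  balance is best effort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import FeatureMatrix

__all__ = [
    "DiscretizationScheme",
    "equal_frequency_cutpoints",
    "categorize",
    "threshold_vocabulary",
    "DEFAULT_BINS",
]

#: Default number of categories when the caller does not choose one.
DEFAULT_BINS = 4


@dataclass(frozen=True)
class DiscretizationScheme:
    """Cutpoints dividing one protein's values into ordered categories."""

    protein_id: str
    cutpoints: tuple[float, ...]
    source: str  # "equal_frequency" | "user"

    def __post_init__(self) -> None:
        if self.source not in ("equal_frequency", "user"):
            raise ValueError(f"unknown scheme source {self.source!r}")
        if len(self.cutpoints) < 1:
            raise ValueError("scheme needs at least one cutpoint (k >= 2)")
        if any(b <= a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError(f"cutpoints must be strictly ascending: {self.cutpoints}")

    @property
    def n_categories(self) -> int:
        return len(self.cutpoints) + 1

    def to_json(self) -> dict:
        return {
            "protein": self.protein_id,
            "cutpoints": list(self.cutpoints),
            "source": self.source,
        }


def equal_frequency_cutpoints(
    values: Sequence[float], k: int, protein_id: str = ""
) -> DiscretizationScheme:
    """Equal-frequency cutpoints for ``k`` categories.

    Each cutpoint is the midpoint between the adjacent order statistics
    at a bin edge.  Ideal edges sit at ranks ``n*i/k``; when the value at
    an ideal edge is tied across the edge, the edge moves to the nearest
    rank where adjacent values differ, keeping occupancies as balanced
    as the ties allow.

    Raises
    ------
    ValueError
        On non-finite values, ``k < 2``, or fewer than ``k`` distinct
        values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    if k < 2:
        raise ValueError(f"number of categories must be >= 2, got {k}")
    s = np.sort(v)
    n = s.size
    n_distinct = np.unique(s).size
    if n_distinct < k:
        raise ValueError(
            f"need at least {k} distinct values for {k} categories, got {n_distinct}"
        )
    # candidate edges: positions j (1..n-1) where s[j-1] < s[j]
    candidates = np.flatnonzero(s[:-1] < s[1:]) + 1
    cutpoints: list[float] = []
    prev = 0
    for i in range(1, k):
        target = n * i / k
        feasible = candidates[candidates > prev]
        if feasible.size == 0:
            break  # ties exhausted the remaining edges
        j = int(feasible[np.argmin(np.abs(feasible - target))])
        cutpoints.append(float((s[j - 1] + s[j]) / 2))
        prev = j
    return DiscretizationScheme(protein_id, tuple(cutpoints), "equal_frequency")


def categorize(value: float, scheme: DiscretizationScheme) -> int:
    """Category (1..k) of a value: ``1 +`` number of cutpoints strictly
    below it, so a value equal to a cutpoint lands in the lower bin."""
    if not math.isfinite(value):
        raise ValueError(f"cannot categorise non-finite value {value!r}")
    return 1 + int(np.sum(np.asarray(scheme.cutpoints) < value))


def threshold_vocabulary(
    matrix: FeatureMatrix,
    k: int = DEFAULT_BINS,
    user_cutoffs: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, list[float]]:
    """Candidate rule thresholds per protein.

    Equal-frequency cutpoints at ``k`` categories by default; a protein
    listed in ``user_cutoffs`` uses exactly the given ascending list
    instead.  Proteins with too few distinct observed values to support
    ``k`` bins fall back to as many bins as the data allow (at least 2
    distinct values required; otherwise the protein is omitted).
    """
    user_cutoffs = dict(user_cutoffs or {})
    vocab: dict[str, list[float]] = {}
    for pid in matrix.protein_ids:
        if pid in user_cutoffs:
            cuts = [float(c) for c in user_cutoffs.pop(pid)]
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"user cut-offs for {pid!r} must be strictly ascending: {cuts}")
            if not cuts:
                raise ValueError(f"user cut-offs for {pid!r} must be non-empty")
            vocab[pid] = cuts
            continue
        col = matrix.column(pid)
        col = col[np.isfinite(col)]
        n_distinct = np.unique(col).size
        if n_distinct < 2:
            continue  # constant feature carries no threshold
        eff_k = min(k, n_distinct)
        scheme = equal_frequency_cutpoints(col, eff_k, pid)
        vocab[pid] = list(scheme.cutpoints)
    if user_cutoffs:
        raise ValueError(
            f"user cut-offs refer to proteins absent from the matrix: {sorted(user_cutoffs)}"
        )
    return vocab
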