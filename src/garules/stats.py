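"""Cohort comparison statistics.

Covers the statistical toolkit of the prognostic analysis: pooled
two-sample Student's t-tests (raw samples or summary form) for
continuous variables, Fisher's exact test for 2x2 contingency tables of
categorical variables, table-style group summaries, and the
verification-stage comparison of measured protein concentrations with
optional outlier exclusion.

All tests are two-sided.  No multiple-testing correction is applied;
p-values are reported raw, as in the analysis this package reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fisher_exact_2x2",
    "fisher_exact_2x2_exact",
    "two_sample_t",
    "two_sample_t_summary",
    "TTestResult",
    "exclude_outliers",
    "OutlierReport",
    "GroupSummary",
    "summarize_groups",
    "verification_compare",
    "VerificationResult",
]


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def _hypergeom_weights(r1: int, c1: int, n: int) -> tuple[int, list[int], int]:
    """Integer weights comb(r1,x)*comb(r2,c1-x) over the support of the
    conditional (hypergeometric) distribution at fixed margins."""
    r2 = n - r1
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    return lo, weights, math.comb(n, c1)


def fisher_margin_pvalues(r1: int, c1: int, n: int) -> dict[int, float]:
    """Two-sided Fisher p-value for every table with the given margins.

    Keys are the top-left cell count ``a`` over its support.  Exact
    integer arithmetic: the p-value of ``a`` is the total probability of
    tables (same margins) whose probability does not exceed that of
    ``a``, and with integer weights the comparison needs no floating
    tolerance.
    """
    lo, weights, total = _hypergeom_weights(r1, c1, n)
    order = sorted(range(len(weights)), key=weights.__getitem__)
    csum = 0
    cum_at_weight: dict[int, int] = {}
    for idx in order:
        csum += weights[idx]
        cum_at_weight[weights[idx]] = csum  # overwritten until the last tie
    return {lo + i: cum_at_weight[w] / total for i, w in enumerate(weights)}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p-value sums the hypergeometric probabilities of all
    tables with the same margins whose probability is less than or equal
    to the observed table's (the conventional probability-mass
    definition).  Computed in exact integer arithmetic, so ties are
    handled without tolerance.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ValueError(f"count {name} must be a non-negative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be at least 1")
    return fisher_margin_pvalues(a + b, a + c, n)[a]


def fisher_exact_2x2_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact rational two-sided Fisher p-value (same definition as
    :func:`fisher_exact_2x2`, returned as a Fraction)."""
    a, b, c, d = int(a), int(b), int(c), int(d)
    lo, weights, total = _hypergeom_weights(a + b, a + c, a + b + c + d)
    w_obs = weights[a - lo]
    return Fraction(sum(w for w in weights if w <= w_obs), total)


# ---------------------------------------------------------------------------
# Student's t-test (pooled variance)
# ---------------------------------------------------------------------------


class TTestResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def two_sample_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TTestResult:
    """Pooled-variance Student's t-test from group summaries.

    Degrees of freedom ``n1 + n2 - 2``.  With zero pooled variance the
    test is degenerate: equal means give ``t = 0, p = 1`` by convention,
    unequal means are an error (an infinite statistic).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return TTestResult(0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(min(p, 1.0)))


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance Student's t-test on two raw samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two finite observations")
    return two_sample_t_summary(
        float(np.mean(x)), float(np.std(x, ddof=1)), int(x.size),
        float(np.mean(y)), float(np.std(y, ddof=1)), int(y.size),
    )


# ---------------------------------------------------------------------------
# Outlier exclusion
# ---------------------------------------------------------------------------

_OUTLIER_DEFAULTS = {"tukey_fence": 1.5, "z_score": 3.0}


@dataclass(frozen=True)
class OutlierReport:
    """Which observations an exclusion pass removed, and by what rule."""

    method: str
    threshold: float
    excluded_indices: tuple[int, ...]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_indices)


def exclude_outliers(
    values: Sequence[float],
    method: str = "tukey_fence",
    threshold: Optional[float] = None,
) -> tuple[list[float], OutlierReport]:
    """Remove extreme observations by Tukey fence or z-score.

    ``tukey_fence`` removes values outside ``[Q1 - k*IQR, Q3 + k*IQR]``
    (default ``k = 1.5``, quartiles by linear interpolation);
    ``z_score`` removes values with ``|x - mean| / sd`` above the
    threshold (default 3, sample sd).  Original order is preserved in
    the output; the report lists the removed positions.
    """
    if method not in _OUTLIER_DEFAULTS:
        raise ValueError(f"unknown outlier method {method!r}")
    k = _OUTLIER_DEFAULTS[method] if threshold is None else float(threshold)
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("outlier exclusion needs at least 4 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if method == "tukey_fence":
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        mask = (v < q1 - k * iqr) | (v > q3 + k * iqr)
    else:
        sd = np.std(v, ddof=1)
        mask = np.zeros(v.size, dtype=bool) if sd == 0 else np.abs(v - np.mean(v)) / sd > k
    if mask.all():
        raise ValueError("outlier exclusion would remove every value")
    report = OutlierReport(method, k, tuple(int(i) for i in np.flatnonzero(mask)))
    return [float(x) for x in v[~mask]], report


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

GROUPS = ("favourable", "unfavourable")


@dataclass(frozen=True)
class GroupSummary:
    """One summary row: per-group statistics and the between-group test.

    ``group_stats`` maps each group to ``{"n": ..., "mean": ...,
    "sd": ...}`` for a continuous variable or ``{"count": ...,
    "denominator": ...}`` for a categorical flag (the denominator is the
    group's non-missing count for that variable, so denominators may
    differ between rows).
    """

    variable: str
    test: str  # "t_test" | "fisher_exact"
    group_stats: dict
    p_value: float
    level: Optional[str] = None  # reported level of a categorical variable

    def percent(self, group: str, decimals: int = 1) -> float:
        """Display-layer percentage for a categorical row."""
        gs = self.group_stats[group]
        return round(100 * gs["count"] / gs["denominator"], decimals)


def _is_flag_series(s: pd.Series) -> bool:
    if s.dtype == bool:
        return True
    vals = set(s.dropna().unique().tolist())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def summarize_groups(cohort: pd.DataFrame, variables: Sequence[str]) -> list[GroupSummary]:
    """Table-style two-group summaries of clinical variables.

    Continuous variables get per-group (n, mean, sd) and a pooled
    t-test; binary flags and two-level text variables get per-group
    (count, denominator) and Fisher's exact test.  Denominators are the
    per-variable non-missing counts.  For a two-level text variable the
    alphabetically first level is the one counted.
    """
    if "course" not in cohort.columns:
        raise ValueError("cohort must carry a 'course' column (favourable/unfavourable)")
    out = []
    for var in variables:
        if var not in cohort.columns:
            raise ValueError(f"variable {var!r} absent from cohort table")
        col = cohort[var]
        if col.dropna().empty:
            raise ValueError(f"variable {var!r} has no non-missing values")
        by_group = {g: col[cohort["course"] == g].dropna() for g in GROUPS}
        level: Optional[str] = None
        if col.dtype == object:
            levels = sorted(col.dropna().unique().tolist())
            if len(levels) > 2:
                raise ValueError(f"categorical variable {var!r} has more than two levels: {levels}")
            level = levels[0]
            flag = {g: (v == level) for g, v in by_group.items()}
            categorical = True
        elif _is_flag_series(col):
            flag = {g: v.astype(bool) for g, v in by_group.items()}
            categorical = True
        else:
            categorical = False
        if categorical:
            counts = {g: int(flag[g].sum()) for g in GROUPS}
            denoms = {g: int(flag[g].size) for g in GROUPS}
            p = fisher_exact_2x2(
                counts["favourable"], denoms["favourable"] - counts["favourable"],
                counts["unfavourable"], denoms["unfavourable"] - counts["unfavourable"],
            )
            stats = {g: {"count": counts[g], "denominator": denoms[g]} for g in GROUPS}
            out.append(GroupSummary(var, "fisher_exact", stats, p, level))
        else:
            x, y = by_group["favourable"].to_numpy(float), by_group["unfavourable"].to_numpy(float)
            res = two_sample_t(x, y)
            stats = {
                g: {
                    "n": int(by_group[g].size),
                    "mean": float(np.mean(by_group[g])),
                    "sd": float(np.std(by_group[g], ddof=1)),
                }
                for g in GROUPS
            }
            out.append(GroupSummary(var, "t_test", stats, res.p_value))
    return out


# ---------------------------------------------------------------------------
# Verification-stage comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VerificationResult:
    """Between-group comparison of one measured protein concentration.

    Carries both the p-value on all measurements and, when exclusion is
    requested, the p-value after removing per-group outliers together
    with the per-group exclusion reports.
    """

    protein: str
    p_all: float
    t_all: float
    p_excluded: Optional[float] = None
    t_excluded: Optional[float] = None
    outliers: dict = field(default_factory=dict)  # group -> OutlierReport

    @property
    def n_excluded(self) -> int:
        return sum(r.n_excluded for r in self.outliers.values())


def verification_compare(
    measurements: pd.DataFrame,
    protein: str,
    exclude: bool = False,
    method: str = "tukey_fence",
    threshold: Optional[float] = None,
) -> VerificationResult:
    """Compare a protein's concentrations between course groups.

    ``measurements`` must have a ``group`` column (favourable /
    unfavourable) and one column per protein.  The comparison is a raw
    pooled t-test; with ``exclude=True`` outliers are removed per group
    first and both p-values are reported.
    """
    if "group" not in measurements.columns:
        raise ValueError("verification table must carry a 'group' column")
    if protein not in measurements.columns:
        raise ValueError(f"protein {protein!r} absent from verification table")
    samples = {}
    for g in GROUPS:
        vals = measurements.loc[measurements["group"] == g, protein].dropna().to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than two measurements for {protein!r}")
        samples[g] = vals
    res_all = two_sample_t(samples["favourable"], samples["unfavourable"])
    if not exclude:
        return VerificationResult(protein, res_all.p_value, res_all.statistic)
    filtered, reports = {}, {}
    for g in GROUPS:
        kept, report = exclude_outliers(samples[g], method, threshold)
        if len(kept) < 2:
            raise ValueError(f"group {g!r} has fewer than two measurements after exclusion")
        filtered[g] = kept
        reports[g] = report
    res_ex = two_sample_t(filtered["favourable"], filtered["unfavourable"])
    return VerificationResult(
        protein, res_all.p_value, res_all.statistic,
        res_ex.p_value, res_ex.statistic, reports,
    )
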