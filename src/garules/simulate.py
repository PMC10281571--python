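"""Synthetic discovery and verification cohorts with planted structure.

The raw data behind the analysis this package reproduces — per-patient
CSF fold-change features and ELISA concentrations — were never
deposited, so every stage is exercised against simulated cohorts that
share the published statistical shape:

* a discovery cohort of 20 unfavourable / 43 favourable patients with
  151 protein fold-change features, into which conjunctive rules are
  *planted*: a chosen fraction of the rule's target class (the
  penetrance) is forced to satisfy every condition, a chosen fraction of
  the other class (the background rate) likewise, and everyone else is
  forced to fail at least one condition.  Because satisfaction is
  enforced by placing feature values on the correct side of each
  threshold, the rule's confusion counts on the synthetic cohort are
  exact by construction;
* clinical covariates drawn with the published group rates (e.g. optic
  nerve involvement in 39.4% of favourable vs 7.4% of unfavourable
  patients);
* a 20/20 verification cohort of protein concentrations with
  configurable group mean shifts and occasional extreme outliers.

Non-planted features are group-independent log-normal noise centred on
a fold change of 1.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import FeatureCache
from .io import FeatureMatrix
from .model import Comparator, Condition, CourseLabel, Rule, parse_rule_text, serialize_rule

__all__ = [
    "PlantedRule",
    "VerificationProtein",
    "VerificationConfig",
    "SimConfig",
    "SyntheticBundle",
    "GroundTruthReport",
    "simulate_discovery",
    "simulate_verification",
    "ground_truth_check",
    "RULE1_TEXT",
    "RULE2_TEXT",
]

#: The two published rules, in the text dialect.
RULE1_TEXT = (
    "ARMSS>=5.0 IF { C3bCfb<=1.0 AND A2M<=2.5 AND ATF7<=1.0 AND PRBP<=1.0 "
    "AND Haptoglobin<=1.0 AND PDS5B<=1.0 AND Myosin<=1.0 }"
)
RULE2_TEXT = "ARMSS<5.0 IF { CD36<=1.0 AND A2M>2.5 AND ApoA1<=1.0 }"


@dataclass(frozen=True)
class PlantedRule:
    """A rule to embed in the feature matrix.

    ``penetrance`` is the fraction of the rule's predicted class forced
    to satisfy it; ``background_rate`` the fraction of the other class.
    A planted rule with penetrance below background would be
    anti-predictive, which is rejected unless that is explicitly wanted
    via a direct feature edit.
    """

    rule: Rule
    penetrance: float
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("penetrance", "background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.penetrance < self.background_rate:
            raise ValueError(
                "penetrance below background rate plants an anti-predictive rule; "
                "swap the rule's predicted class instead"
            )


@dataclass(frozen=True)
class VerificationProtein:
    """Concentration model of one protein in the verification cohort."""

    mean_favourable: float
    sd_favourable: float
    mean_unfavourable: float
    sd_unfavourable: float

    def __post_init__(self) -> None:
        if self.sd_favourable <= 0 or self.sd_unfavourable <= 0:
            raise ValueError("concentration sds must be positive")


def _default_verification_proteins() -> dict[str, VerificationProtein]:
    # Standardised group differences: ~1.1 for the two markers reported
    # significant at n = 20/20, zero for the null marker, and a real
    # shift for haptoglobin that planted outliers are meant to mask.
    return {
        "A2M": VerificationProtein(100.0, 30.0, 133.0, 30.0),
        "ApoA1": VerificationProtein(50.0, 15.0, 66.5, 15.0),
        "CD36": VerificationProtein(10.0, 3.0, 10.0, 3.0),
        "Haptoglobin": VerificationProtein(40.0, 12.0, 56.0, 12.0),
    }


@dataclass(frozen=True)
class VerificationConfig:
    """Generative recipe for the independent verification cohort."""

    n_per_group: int = 20
    proteins: Mapping[str, VerificationProtein] = field(
        default_factory=_default_verification_proteins
    )
    outlier_rate: float = 0.05
    outlier_magnitude: float = 8.0  # displacement in group sds

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("verification groups need at least 2 patients")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")


def _default_planted_rules() -> tuple[PlantedRule, ...]:
    # The published high-specificity rule, at its published coverage:
    # 20 of 43 favourable-course patients satisfy it, no unfavourable
    # patient does.
    return (PlantedRule(parse_rule_text(RULE2_TEXT), penetrance=20 / 43, background_rate=0.0),)


#: Per-flag (favourable, unfavourable) rates of the published cohort.
CLINICAL_RATES: dict[str, tuple[float, float]] = {
    "lesion_cerebral_high_load": (0.076, 0.259),
    "lesion_optic_nerve": (0.394, 0.074),
    "lesion_brainstem": (0.227, 0.296),
    "lesion_spinal_cord": (0.288, 0.296),
    "lesion_multifocal": (0.015, 0.074),
    "symptom_sensory": (0.318, 0.195),
    "symptom_motor": (0.125, 0.195),
    "symptom_gait": (0.045, 0.171),
    "symptom_optic_neuritis": (0.261, 0.049),
    "symptom_brainstem_other": (0.193, 0.244),
    "symptom_bladder_bowel": (0.011, 0.122),
    "symptom_lhermitte": (0.045, 0.024),
}


@dataclass(frozen=True)
class SimConfig:
    """Generative recipe for a full synthetic study.

    Defaults match the published study shape: 20 unfavourable / 43
    favourable discovery patients (the group totals entering the rules'
    confusion arithmetic), 151 protein features, the high-specificity
    rule planted at its published coverage, clinical flags at the
    published group rates, and a 20/20 verification cohort.
    """

    n_unfavourable: int = 20
    n_favourable: int = 43
    n_proteins: int = 151
    planted_rules: tuple[PlantedRule, ...] = field(default_factory=_default_planted_rules)
    feature_log_sigma: float = 0.4  # log-normal scale of background features
    clinical_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CLINICAL_RATES)
    )
    verification: VerificationConfig = field(default_factory=VerificationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unfavourable < 2 or self.n_favourable < 2:
            raise ValueError("each course group needs at least 2 patients")
        if self.feature_log_sigma <= 0:
            raise ValueError("feature_log_sigma must be positive")
        for flag, (pf, pu) in self.clinical_effects.items():
            if not (0 <= pf <= 1 and 0 <= pu <= 1):
                raise ValueError(f"clinical rates for {flag!r} must lie in [0, 1]")
        planted_proteins: set[str] = set()
        for pr in self.planted_rules:
            overlap = planted_proteins & pr.rule.proteins
            if overlap:
                raise ValueError(
                    f"planted rules share proteins {sorted(overlap)}; "
                    "planting would conflict"
                )
            planted_proteins |= pr.rule.proteins


@dataclass(frozen=True)
class SyntheticBundle:
    """A simulated study: tables plus the ground truth that generated them."""

    cohort: pd.DataFrame
    features: FeatureMatrix
    verification: pd.DataFrame
    truth: dict


#: Relative bands for planted-value placement: a value forced below a
#: positive threshold t is drawn from t*U(*BELOW_BAND*), one forced above
#: from t*U(*ABOVE_BAND*).  The wide margins keep the two sides of every
#: planted condition separated by a broad gap on the fold-change scale
#: (a large effect size), so thresholds anywhere in the gap classify the
#: cohort identically.
BELOW_BAND = (0.2, 0.55)
ABOVE_BAND = (1.15, 2.5)


def _below(t: float, rng: np.random.Generator, size: int) -> np.ndarray:
    if t > 0:
        return t * rng.uniform(*BELOW_BAND, size)
    return t - rng.uniform(0.1, 1.0, size)


def _above(t: float, rng: np.random.Generator, size: int) -> np.ndarray:
    if t > 0:
        return t * rng.uniform(*ABOVE_BAND, size)
    return t + rng.uniform(0.1, 1.0, size)


def _place(cond: Condition, satisfy: bool, rng: np.random.Generator, size: int) -> np.ndarray:
    want_low = (cond.comparator is Comparator.LE) == satisfy
    return _below(cond.threshold, rng, size) if want_low else _above(cond.threshold, rng, size)


def simulate_discovery(config: SimConfig) -> SyntheticBundle:
    """Generate a full synthetic study bundle.

    ARMSS scores are drawn uniformly on [5, 10] (unfavourable) and
    [0, 5) (favourable) so the label split matches the configured group
    sizes exactly.  For each planted rule, ``round(penetrance * T)``
    target-class and ``round(background_rate * F)`` other-class patients
    are forced to satisfy every condition; every other patient fails a
    uniformly chosen non-empty subset of the conditions.  The planted
    confusion counts are therefore exact.
    """
    rng = np.random.default_rng(config.seed)
    n_u, n_f = config.n_unfavourable, config.n_favourable
    n = n_u + n_f
    ids = [f"P{i + 1:03d}" for i in range(n)]
    unfav_mask = np.zeros(n, dtype=bool)
    unfav_mask[rng.choice(n, size=n_u, replace=False)] = True

    cohort = _simulate_clinical(config, rng, ids, unfav_mask)
    features, rule_truth = _simulate_features(config, rng, ids, unfav_mask)
    verification, outlier_truth = simulate_verification(config, rng=rng)
    truth = {
        "labels": {pid: ("unfavourable" if u else "favourable") for pid, u in zip(ids, unfav_mask)},
        "planted_rules": rule_truth,
        "verification_outliers": outlier_truth,
    }
    return SyntheticBundle(cohort, features, verification, truth)


def _edss_grid(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 2) / 2, 0.0, 10.0)


def _simulate_clinical(
    config: SimConfig, rng: np.random.Generator, ids: list[str], unfav: np.ndarray
) -> pd.DataFrame:
    n = len(ids)
    fav = ~unfav
    armss = np.empty(n)
    armss[unfav] = rng.uniform(5.0, 10.0, unfav.sum())
    armss[fav] = rng.uniform(0.0, 5.0, fav.sum())
    armss = np.round(armss, 2)
    armss[unfav] = np.maximum(armss[unfav], 5.0)
    armss[fav] = np.minimum(armss[fav], 4.99)

    def bimodal(mean_f, sd_f, mean_u, sd_u, lo, hi):
        out = np.empty(n)
        out[fav] = rng.normal(mean_f, sd_f, fav.sum())
        out[unfav] = rng.normal(mean_u, sd_u, unfav.sum())
        return np.clip(out, lo, hi)

    cohort = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    cohort["age"] = np.round(bimodal(41.9, 9.9, 44.2, 9.8, 18, 75), 1)
    cohort["sex"] = np.where(
        rng.random(n) < np.where(unfav, 0.63, 0.716), "female", "male"
    )
    cohort["follow_up"] = np.round(bimodal(8.04, 2.15, 8.63, 2.65, 5.0, 15.0), 2)
    cohort["edss_tap"] = _edss_grid(bimodal(0.61, 0.76, 2.13, 1.84, 0, 10))
    cohort["edss_last"] = _edss_grid(bimodal(0.94, 1.01, 4.8, 1.95, 0, 10))
    cohort["armss"] = armss
    cohort["ocb_positive"] = (rng.random(n) < np.where(unfav, 0.96, 0.774)).astype(int)
    cohort["igg_index"] = np.round(bimodal(0.89, 0.62, 1.21, 0.87, 0.3, 4.0), 2)
    cohort["dmt_initiated"] = (rng.random(n) < np.where(unfav, 1.0, 0.808)).astype(int)
    for flag, (p_f, p_u) in config.clinical_effects.items():
        cohort[flag] = (rng.random(n) < np.where(unfav, p_u, p_f)).astype(int)
    cohort["course"] = np.where(unfav, "unfavourable", "favourable")
    return cohort


def _simulate_features(
    config: SimConfig, rng: np.random.Generator, ids: list[str], unfav: np.ndarray
) -> tuple[FeatureMatrix, list[dict]]:
    n = len(ids)
    planted_proteins = sorted({p for pr in config.planted_rules for p in pr.rule.proteins})
    n_noise = config.n_proteins - len(planted_proteins)
    if n_noise < 0:
        raise ValueError(
            f"n_proteins={config.n_proteins} below the {len(planted_proteins)} planted proteins"
        )
    names = planted_proteins + [f"PROT{i + 1:03d}" for i in range(n_noise)]
    values = pd.DataFrame(
        np.exp(rng.normal(0.0, config.feature_log_sigma, (n, len(names)))),
        index=pd.Index(ids, name="patient_id"),
        columns=names,
    )

    rule_truth = []
    for pr in config.planted_rules:
        target_unfav = pr.rule.predicted_class is CourseLabel.UNFAVOURABLE
        target_idx = np.flatnonzero(unfav == target_unfav)
        other_idx = np.flatnonzero(unfav != target_unfav)
        n_sat_t = int(round(pr.penetrance * target_idx.size))
        n_sat_o = int(round(pr.background_rate * other_idx.size))
        sat_t = rng.choice(target_idx, size=n_sat_t, replace=False)
        sat_o = rng.choice(other_idx, size=n_sat_o, replace=False)
        satisfied = np.zeros(n, dtype=bool)
        satisfied[sat_t] = True
        satisfied[sat_o] = True
        conds = pr.rule.conditions
        for i in np.flatnonzero(satisfied):
            for cond in conds:
                values.iloc[i, values.columns.get_loc(cond.protein_id)] = _place(
                    cond, True, rng, 1
                )[0]
        for i in np.flatnonzero(~satisfied):
            # fail a uniformly chosen non-empty subset of conditions
            failing = rng.random(len(conds)) < 0.5
            if not failing.any():
                failing[int(rng.integers(len(conds)))] = True
            for cond, fail in zip(conds, failing):
                values.iloc[i, values.columns.get_loc(cond.protein_id)] = _place(
                    cond, not fail, rng, 1
                )[0]
        rule_truth.append(
            {
                "rule": serialize_rule(pr.rule),
                "penetrance": pr.penetrance,
                "background_rate": pr.background_rate,
                "satisfied_patients": sorted(ids[i] for i in np.flatnonzero(satisfied)),
            }
        )
    return FeatureMatrix(values.round(6)), rule_truth


def simulate_verification(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Generate the verification-cohort concentration table.

    Per protein and group, concentrations are normal with the configured
    mean and sd, truncated at zero.  Each measurement is independently
    displaced upward by ``outlier_magnitude`` group sds with probability
    ``outlier_rate``; the displaced (protein, patient) pairs are the
    returned outlier ground truth.
    """
    vc = config.verification
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = vc.n_per_group
    ids = [f"V{i + 1:03d}" for i in range(2 * m)]
    groups = ["favourable"] * m + ["unfavourable"] * m
    table = pd.DataFrame({"group": groups}, index=pd.Index(ids, name="patient_id"))
    outliers: list[dict] = []
    for protein, model in vc.proteins.items():
        col = np.empty(2 * m)
        for sl, mean, sd in (
            (slice(0, m), model.mean_favourable, model.sd_favourable),
            (slice(m, 2 * m), model.mean_unfavourable, model.sd_unfavourable),
        ):
            draws = rng.normal(mean, sd, m)
            while True:  # truncate at zero by redrawing
                neg = draws <= 0
                if not neg.any():
                    break
                draws[neg] = rng.normal(mean, sd, int(neg.sum()))
            displaced = rng.random(m) < vc.outlier_rate
            draws[displaced] += vc.outlier_magnitude * sd
            col[sl] = draws
            base = sl.start
            outliers.extend(
                {"protein": protein, "patient_id": ids[base + int(i)]}
                for i in np.flatnonzero(displaced)
            )
        table[protein] = np.round(col, 4)
    return table, outliers


@dataclass(frozen=True)
class GroundTruthReport:
    passed: bool
    failures: tuple[str, ...]


def ground_truth_check(bundle: SyntheticBundle) -> GroundTruthReport:
    """Verify a bundle's stored ground truth against its emitted tables.

    Re-evaluates each planted rule on the feature matrix and compares
    the satisfied patient set with the stored one; checks each recorded
    verification outlier still sits beyond its group's Tukey fence
    (computed from the remaining values).  Failures name the offending
    patient and protein.
    """
    failures: list[str] = []
    cache = FeatureCache(bundle.features)
    ids = bundle.features.patient_ids
    for entry in bundle.truth["planted_rules"]:
        rule = parse_rule_text(entry["rule"])
        sat, _ = cache.rule_sat(rule)
        observed = {ids[i] for i in np.flatnonzero(sat)}
        stored = set(entry["satisfied_patients"])
        for pid in sorted(observed ^ stored):
            state = "satisfies" if pid in observed else "no longer satisfies"
            failures.append(f"patient {pid} {state} planted rule {entry['rule']!r}")
    table = bundle.verification
    for rec in bundle.truth["verification_outliers"]:
        protein, pid = rec["protein"], rec["patient_id"]
        group = table.loc[pid, "group"]
        vals = table.loc[table["group"] == group, protein]
        rest = vals.drop(index=pid).to_numpy(float)
        q1, q3 = np.percentile(rest, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        low_fence = q1 - 1.5 * (q3 - q1)
        v = float(table.loc[pid, protein])
        if low_fence <= v <= fence:
            failures.append(
                f"recorded outlier {protein}/{pid} is not extreme within its group"
            )
    return GroundTruthReport(not failures, tuple(failures))
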