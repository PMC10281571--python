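"""Genetic-algorithm search over conjunctive threshold rules.

The search maintains a population of candidate rules ("hypotheses"),
scores each against the cohort with a user-chosen fitness function,
carries the fittest ``survivors`` unchanged into the next generation
(truncation selection with elitism), and refills the population by
single-point crossover of survivor pairs followed by per-condition
mutation.  Candidate thresholds are restricted to the discretisation
vocabulary, so the search space is finite and an exhaustive oracle is
available for small instances.

Everything is deterministic given the seed in :class:`GAConfig`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .engine import (
    ConfusionCounts,
    FeatureCache,
    RulePerformance,
    _labels_array,
    performance,
)
from .io import FeatureMatrix
from .model import Comparator, Condition, CourseLabel, Rule

__all__ = [
    "FitnessSpec",
    "GAConfig",
    "MinedRuleSet",
    "fitness",
    "init_population",
    "mutate",
    "crossover",
    "run_ga",
    "exhaustive_search",
]

_FITNESS_KINDS = ("weighted_sens_spec", "accuracy", "kappa", "youden")


@dataclass(frozen=True)
class FitnessSpec:
    """Which scalar a rule is optimised for.

    ``weighted_sens_spec`` scores ``(w_sens*sens + w_spec*spec) /
    (w_sens + w_spec)``; tilting the weights trades sensitivity against
    specificity, which is how rules of different character are obtained
    from the same cohort.  ``youden`` is ``sens + spec - 1``.  A rule
    with any required metric undefined scores 0, so degenerate rules
    (always-true, always-false) are never selected.
    """

    kind: str = "weighted_sens_spec"
    w_sens: float = 1.0
    w_spec: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _FITNESS_KINDS:
            raise ValueError(f"unknown fitness kind {self.kind!r}; choose from {_FITNESS_KINDS}")
        if self.kind == "weighted_sens_spec":
            if self.w_sens < 0 or self.w_spec < 0 or self.w_sens + self.w_spec <= 0:
                raise ValueError("weights must be >= 0 with positive sum")


def fitness(perf: RulePerformance, spec: FitnessSpec) -> float:
    """Scalar score of a rule's performance under a fitness spec."""
    if spec.kind == "weighted_sens_spec":
        if perf.sensitivity is None or perf.specificity is None:
            return 0.0
        return (spec.w_sens * perf.sensitivity + spec.w_spec * perf.specificity) / (
            spec.w_sens + spec.w_spec
        )
    if spec.kind == "accuracy":
        return 0.0 if perf.accuracy is None else perf.accuracy
    if spec.kind == "kappa":
        return 0.0 if perf.kappa is None else perf.kappa
    # youden
    if perf.sensitivity is None or perf.specificity is None:
        return 0.0
    return perf.sensitivity + perf.specificity - 1.0


@dataclass(frozen=True)
class GAConfig:
    """Knobs of the evolutionary search.

    Defaults: a population of 200 hypotheses of which the top 20 survive
    each generation, per-condition mutation rate 0.1, crossover rate
    0.7, 100 generations, and at most 7 conditions per rule.
    """

    population_size: int = 200
    survivors: int = 20
    mutation_rate: float = 0.1
    crossover_rate: float = 0.7
    generations: int = 100
    max_conditions: int = 7
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    target_class: CourseLabel = CourseLabel.UNFAVOURABLE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.survivors < self.population_size:
            raise ValueError("need 1 <= survivors < population_size")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.max_conditions < 1:
            raise ValueError("max_conditions must be >= 1")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class MinedRuleSet:
    """Distinct top rules with their performance and fitness, sorted
    by fitness descending; ties broken by canonical rule text."""

    rules: tuple[tuple[Rule, RulePerformance, float], ...]
    config: GAConfig
    generations_run: int
    best_fitness_history: tuple[float, ...]

    @property
    def best(self) -> tuple[Rule, RulePerformance, float]:
        return self.rules[0]


Vocabulary = Mapping[str, Sequence[float]]


def _triples(vocabulary: Vocabulary) -> list[tuple[str, Comparator, float]]:
    """Deterministically ordered (protein, comparator, threshold) pool."""
    out = []
    for pid in sorted(vocabulary):
        for t in vocabulary[pid]:
            out.append((pid, Comparator.LE, float(t)))
            out.append((pid, Comparator.GT, float(t)))
    if not out:
        raise ValueError("empty threshold vocabulary: nothing to search over")
    return out


def _consistent_with(cond: Condition, others: Sequence[Condition]) -> bool:
    try:
        Rule(list(others) + [cond], CourseLabel.FAVOURABLE)
        return True
    except ValueError:
        return False


def _sample_condition(
    pool: Sequence[tuple[str, Comparator, float]],
    rng: np.random.Generator,
    existing: Sequence[Condition] = (),
    tries: int = 30,
) -> Optional[Condition]:
    """Uniform draw from the pool, rejecting duplicates/contradictions."""
    for _ in range(tries):
        pid, comp, thr = pool[int(rng.integers(len(pool)))]
        cond = Condition(pid, comp, thr)
        if cond in existing:
            continue
        if _consistent_with(cond, existing):
            return cond
    return None


def init_population(vocabulary: Vocabulary, config: GAConfig, rng: np.random.Generator) -> list[Rule]:
    """Random initial rules: 1..max_conditions conditions drawn
    uniformly over the (protein, comparator, threshold) pool, without
    duplicate or contradictory condition pairs."""
    pool = _triples(vocabulary)
    population = []
    for _ in range(config.population_size):
        n_cond = int(rng.integers(1, config.max_conditions + 1))
        conds: list[Condition] = []
        for _ in range(n_cond):
            cond = _sample_condition(pool, rng, conds)
            if cond is None:
                break
            conds.append(cond)
        if not conds:  # vocabulary so small every extension failed
            pid, comp, thr = pool[int(rng.integers(len(pool)))]
            conds = [Condition(pid, comp, thr)]
        population.append(Rule(conds, config.target_class))
    return population


def mutate(
    rule: Rule,
    vocabulary: Vocabulary,
    rate: float,
    rng: np.random.Generator,
    max_conditions: int | None = None,
) -> Rule:
    """Point-mutate a rule.

    Each condition independently, with probability ``rate``, has its
    threshold, comparator, or protein resampled from the vocabulary;
    then with probability ``rate`` a condition is added (below the cap)
    or dropped (above one condition).  The result always satisfies the
    rule invariants; a mutation that cannot be made consistent leaves
    the condition unchanged.
    """
    pool = _triples(vocabulary)
    conds = list(rule.conditions)
    for i in range(len(conds)):
        if rng.random() >= rate:
            continue
        others = conds[:i] + conds[i + 1 :]
        aspect = ("threshold", "comparator", "protein")[int(rng.integers(3))]
        new = None
        for _ in range(30):
            c = conds[i]
            if aspect == "comparator":
                cand = Condition(
                    c.protein_id,
                    Comparator.GT if c.comparator is Comparator.LE else Comparator.LE,
                    c.threshold,
                )
            elif aspect == "threshold":
                opts = list(vocabulary.get(c.protein_id, []))
                if len(opts) <= 1:
                    break
                cand = Condition(c.protein_id, c.comparator, float(opts[int(rng.integers(len(opts)))]))
            else:  # protein move: fresh draw from the whole pool
                pid, comp, thr = pool[int(rng.integers(len(pool)))]
                cand = Condition(pid, comp, thr)
            if cand != c and cand not in others and _consistent_with(cand, others):
                new = cand
                break
        if new is not None:
            conds[i] = new
    if rng.random() < rate:
        can_add = max_conditions is None or len(conds) < max_conditions
        can_drop = len(conds) > 1
        ops = [op for op, ok in (("add", can_add), ("drop", can_drop)) if ok]
        if ops:
            op = ops[int(rng.integers(len(ops)))]
            if op == "add":
                cond = _sample_condition(pool, rng, conds)
                if cond is not None:
                    conds.append(cond)
            else:
                del conds[int(rng.integers(len(conds)))]
    return Rule(conds, rule.predicted_class)


def _repair(conds: Sequence[Condition], max_conditions: int | None) -> list[Condition]:
    """Drop later duplicates and later contradictory conditions; cap length."""
    kept: list[Condition] = []
    for c in conds:
        if c in kept:
            continue
        if _consistent_with(c, kept):
            kept.append(c)
    if max_conditions is not None:
        kept = kept[:max_conditions]
    return kept


def crossover(
    a: Rule,
    b: Rule,
    rng: np.random.Generator,
    max_conditions: int | None = None,
) -> tuple[Rule, Rule]:
    """Single-point exchange of condition sublists between two rules.

    Both parents must predict the same class.  The shared cut position
    makes ``crossover(a, a)`` the identity; contradictions introduced by
    mixing are repaired by dropping the later condition, so offspring
    conditions are always a subset of the parents' union.
    """
    if a.predicted_class is not b.predicted_class:
        raise ValueError("crossover requires both parents to target the same class")
    la, lb = len(a.conditions), len(b.conditions)
    cut = int(rng.integers(0, max(la, lb) + 1))
    i, j = min(cut, la), min(cut, lb)
    c1 = _repair(list(a.conditions[:i]) + list(b.conditions[j:]), max_conditions)
    c2 = _repair(list(b.conditions[:j]) + list(a.conditions[i:]), max_conditions)
    if not c1:
        c1 = [a.conditions[0]]
    if not c2:
        c2 = [b.conditions[0]]
    return Rule(c1, a.predicted_class), Rule(c2, b.predicted_class)


class _Evaluator:
    """Memoised rule evaluation over a fixed cohort."""

    def __init__(self, matrix: FeatureMatrix, labels, fitness_spec: FitnessSpec):
        self.cache = FeatureCache(matrix)
        self.unfav = _labels_array(labels, self.cache.patient_ids)
        self.spec = fitness_spec
        self._memo: dict[tuple, tuple[RulePerformance, float]] = {}

    def __call__(self, rule: Rule) -> tuple[RulePerformance, float]:
        key = rule.canonical_key()
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        positive = self.unfav if rule.predicted_class is CourseLabel.UNFAVOURABLE else ~self.unfav
        sat, missing = self.cache.rule_sat(rule)
        keep = ~missing
        counts = ConfusionCounts(
            tp=int(np.sum(sat & positive & keep)),
            fn=int(np.sum(~sat & positive & keep)),
            fp=int(np.sum(sat & ~positive & keep)),
            tn=int(np.sum(~sat & ~positive & keep)),
            excluded=int(np.sum(missing)),
        )
        perf = performance(counts)
        score = fitness(perf, self.spec)
        result = (perf, score)
        self._memo[key] = result
        return result


def _rank_key(item: tuple[Rule, RulePerformance, float]):
    rule, _, score = item
    return (-score, rule.canonical_key())


def run_ga(
    matrix: FeatureMatrix,
    labels,
    vocabulary: Vocabulary,
    config: GAConfig,
) -> MinedRuleSet:
    """Evolve conjunctive rules against a labelled cohort.

    Elitist loop: evaluate the population, keep the ``survivors``
    fittest rules unchanged, refill by crossover of random survivor
    pairs (with probability ``crossover_rate``, else cloning) followed
    by mutation.  The best fitness is therefore non-decreasing across
    generations.  Returns the distinct top rules, best first.

    Raises ``ValueError`` when the cohort has fewer than two patients
    in either course group.
    """
    unfav = _labels_array(labels, matrix.patient_ids)
    n_unfav = int(unfav.sum())
    if n_unfav < 2 or len(unfav) - n_unfav < 2:
        raise ValueError(
            "rule mining needs at least two patients in each course group; "
            f"got {n_unfav} unfavourable / {len(unfav) - n_unfav} favourable"
        )
    rng = np.random.default_rng(config.seed)
    evaluate = _Evaluator(matrix, labels, config.fitness)
    population = init_population(vocabulary, config, rng)
    history: list[float] = []
    ranked: list[tuple[Rule, RulePerformance, float]] = []
    for _ in range(config.generations):
        ranked = sorted(((r, *evaluate(r)) for r in population), key=_rank_key)
        best = ranked[0][2]
        if history and best < history[-1]:  # elitism guarantees this never fires
            raise AssertionError("best fitness decreased despite elitism")
        history.append(best)
        # survivors are the top *distinct* rules: truncation selection on a
        # deduplicated ranking, which preserves elitism while keeping the
        # breeding pool diverse
        elite = []
        seen_keys: set[tuple] = set()
        for r, _, _ in ranked:
            key = r.canonical_key()
            if key in seen_keys:
                continue
            seen_keys.add(key)
            elite.append(r)
            if len(elite) >= config.survivors:
                break
        children: list[Rule] = []
        while len(children) < config.population_size - len(elite):
            pa = elite[int(rng.integers(len(elite)))]
            pb = elite[int(rng.integers(len(elite)))]
            if rng.random() < config.crossover_rate:
                ca, cb = crossover(pa, pb, rng, config.max_conditions)
            else:
                ca, cb = pa, pb
            for child in (ca, cb):
                if len(children) < config.population_size - len(elite):
                    children.append(
                        mutate(child, vocabulary, config.mutation_rate, rng, config.max_conditions)
                    )
        population = elite + children
    ranked = sorted(((r, *evaluate(r)) for r in population), key=_rank_key)
    history.append(ranked[0][2])
    seen: set[tuple] = set()
    top: list[tuple[Rule, RulePerformance, float]] = []
    for item in ranked:
        key = item[0].canonical_key()
        if key in seen:
            continue
        seen.add(key)
        top.append(item)
        if len(top) >= config.survivors:
            break
    return MinedRuleSet(tuple(top), config, config.generations, tuple(history))


#: Guard on the exhaustive oracle's search-space size.
EXHAUSTIVE_GUARD = 1_000_000


def exhaustive_search(
    matrix: FeatureMatrix,
    labels,
    vocabulary: Vocabulary,
    max_conditions: int,
    fitness_spec: FitnessSpec,
    classes: Sequence[CourseLabel] = (CourseLabel.FAVOURABLE, CourseLabel.UNFAVOURABLE),
) -> tuple[Rule, float]:
    """Enumerate every rule up to ``max_conditions`` and return the best.

    Serves as the ground-truth oracle for validating the heuristic
    search on small instances.  Ties are broken lexicographically on the
    canonical rule key, so the result is deterministic.  Raises when the
    search space exceeds one million rules.
    """
    pool = _triples(vocabulary)
    m = len(pool)
    space = len(classes) * sum(math.comb(m, j) for j in range(1, max_conditions + 1))
    if space > EXHAUSTIVE_GUARD:
        raise ValueError(
            f"search space of {space} rules exceeds the exhaustive guard "
            f"({EXHAUSTIVE_GUARD}); use run_ga instead"
        )
    evaluators = {cls: _Evaluator(matrix, labels, fitness_spec) for cls in classes}
    best: tuple[float, tuple, Rule] | None = None
    for size in range(1, max_conditions + 1):
        for combo in itertools.combinations(pool, size):
            conds = [Condition(p, c, t) for p, c, t in combo]
            try:
                rules = {cls: Rule(conds, cls) for cls in classes}
            except ValueError:
                continue  # contradictory conjunction
            for cls, rule in rules.items():
                _, score = evaluators[cls](rule)
                key = (-score, rule.canonical_key())
                if best is None or key < (-best[0], best[2].canonical_key()):
                    best = (score, rule.canonical_key(), rule)
    assert best is not None
    return best[2], best[0]
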