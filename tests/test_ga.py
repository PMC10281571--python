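"""Genetic-algorithm operators, determinism and search quality."""

import numpy as np
import pytest

from garules import (
    Comparator,
    Condition,
    ConfusionCounts,
    CourseLabel,
    FitnessSpec,
    GAConfig,
    Rule,
    crossover,
    exhaustive_search,
    fitness,
    init_population,
    mutate,
    performance,
    run_ga,
    threshold_vocabulary,
)

from conftest import make_matrix
from oracles import enumerate_rules_scores

VOCAB = {"A2M": [1.0, 2.5], "CD36": [1.0], "ApoA1": [1.0, 1.5]}


def _valid(rule: Rule) -> bool:
    try:
        Rule(rule.conditions, rule.predicted_class)
        return True
    except ValueError:
        return False


class TestFitness:
    def test_balanced_weights_equal_two_point_auc(self):
        # the published high-sensitivity rule scores its printed ROC AUC
        perf = performance(ConfusionCounts(15, 5, 1, 42))
        assert fitness(perf, FitnessSpec("weighted_sens_spec", 1, 1)) == pytest.approx(297 / 344)

    def test_perfect_rule_scores_one(self):
        perf = performance(ConfusionCounts(10, 0, 0, 10))
        for spec in (FitnessSpec(), FitnessSpec("accuracy"), FitnessSpec("kappa")):
            assert fitness(perf, spec) == 1.0
        assert fitness(perf, FitnessSpec("youden")) == 1.0

    def test_always_true_rule_scores_zero_under_youden(self):
        perf = performance(ConfusionCounts(10, 0, 10, 0))
        assert fitness(perf, FitnessSpec("youden")) == 0.0

    def test_undefined_metric_scores_zero(self):
        perf = performance(ConfusionCounts(0, 0, 5, 5))  # sensitivity undefined
        assert fitness(perf, FitnessSpec()) == 0.0
        assert fitness(perf, FitnessSpec("kappa")) == 0.0

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            FitnessSpec("weighted_sens_spec", 0, 0)
        with pytest.raises(ValueError):
            FitnessSpec("harmonic")


class TestInitPopulation:
    def test_seed_determinism(self):
        cfg = GAConfig(population_size=50, survivors=5, seed=99)
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        p1 = init_population(VOCAB, cfg, rng1)
        p2 = init_population(VOCAB, cfg, rng2)
        assert p1 == p2
        assert len(p1) == 50

    def test_single_condition_cap(self):
        cfg = GAConfig(population_size=30, survivors=3, max_conditions=1)
        pop = init_population(VOCAB, cfg, np.random.default_rng(0))
        assert all(len(r.conditions) == 1 for r in pop)

    def test_no_contradictory_pairs_across_seeds(self):
        cfg = GAConfig(population_size=40, survivors=4, max_conditions=4)
        for seed in range(30):
            for rule in init_population(VOCAB, cfg, np.random.default_rng(seed)):
                assert _valid(rule)
                assert 1 <= len(rule.conditions) <= 4

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            init_population({}, GAConfig(population_size=10, survivors=2), np.random.default_rng(0))


class TestMutate:
    RULE = Rule(
        [Condition("A2M", Comparator.GT, 1.0), Condition("CD36", Comparator.LE, 1.0)],
        CourseLabel.UNFAVOURABLE,
    )

    def test_zero_rate_is_identity(self):
        for seed in range(10):
            assert mutate(self.RULE, VOCAB, 0.0, np.random.default_rng(seed), 4) == self.RULE

    def test_full_rate_usually_changes_single_condition_rule(self):
        rule = Rule([Condition("A2M", Comparator.GT, 1.0)], CourseLabel.UNFAVOURABLE)
        changed = sum(
            mutate(rule, VOCAB, 1.0, np.random.default_rng(seed), 3) != rule
            for seed in range(200)
        )
        assert changed >= 180

    def test_output_always_valid(self):
        for seed in range(100):
            out = mutate(self.RULE, VOCAB, 0.7, np.random.default_rng(seed), 4)
            assert _valid(out)
            assert 1 <= len(out.conditions) <= 4
            assert out.predicted_class is self.RULE.predicted_class


class TestCrossover:
    A = Rule(
        [Condition("A2M", Comparator.GT, 1.0), Condition("CD36", Comparator.LE, 1.0)],
        CourseLabel.FAVOURABLE,
    )
    B = Rule(
        [Condition("ApoA1", Comparator.LE, 1.5), Condition("A2M", Comparator.LE, 2.5)],
        CourseLabel.FAVOURABLE,
    )

    def test_self_crossover_is_identity(self):
        for seed in range(20):
            c1, c2 = crossover(self.A, self.A, np.random.default_rng(seed))
            assert set(c1.conditions) == set(self.A.conditions)
            assert set(c2.conditions) == set(self.A.conditions)

    def test_offspring_subset_of_parent_union(self):
        union = set(self.A.conditions) | set(self.B.conditions)
        for seed in range(100):
            c1, c2 = crossover(self.A, self.B, np.random.default_rng(seed), max_conditions=3)
            for child in (c1, c2):
                assert _valid(child)
                assert set(child.conditions) <= union
                assert 1 <= len(child.conditions) <= 3

    def test_mismatched_classes_rejected(self):
        other = Rule([Condition("A2M", Comparator.GT, 1.0)], CourseLabel.UNFAVOURABLE)
        with pytest.raises(ValueError):
            crossover(self.A, other, np.random.default_rng(0))


class TestRunGA:
    def _cohort(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        labels = [CourseLabel.UNFAVOURABLE] * (n // 3) + [CourseLabel.FAVOURABLE] * (n - n // 3)
        values = rng.lognormal(0, 0.4, (n, 5))
        # G01 separates perfectly at 1.5 for the unfavourable class
        values[: n // 3, 0] = rng.uniform(1.8, 3.0, n // 3)
        values[n // 3 :, 0] = rng.uniform(0.3, 1.2, n - n // 3)
        return make_matrix(values), labels

    def test_seed_determinism(self):
        matrix, labels = self._cohort()
        vocab = threshold_vocabulary(matrix, 3)
        cfg = GAConfig(population_size=40, survivors=8, generations=10, max_conditions=3, seed=5)
        r1 = run_ga(matrix, labels, vocab, cfg)
        r2 = run_ga(matrix, labels, vocab, cfg)
        assert [(a.canonical_key(), f) for a, _, f in r1.rules] == [
            (a.canonical_key(), f) for a, _, f in r2.rules
        ]
        assert r1.best_fitness_history == r2.best_fitness_history

    def test_elitism_best_fitness_monotone(self):
        matrix, labels = self._cohort(seed=3)
        vocab = threshold_vocabulary(matrix, 3)
        cfg = GAConfig(population_size=40, survivors=8, generations=15, max_conditions=3, seed=2)
        res = run_ga(matrix, labels, vocab, cfg)
        hist = res.best_fitness_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_planted_separator_found(self):
        for seed in range(6):
            matrix, labels = self._cohort(seed=seed, n=36)
            vocab = threshold_vocabulary(matrix, 3)
            cfg = GAConfig(
                population_size=100, survivors=10, generations=50, max_conditions=3,
                mutation_rate=0.2, target_class=CourseLabel.UNFAVOURABLE, seed=seed,
            )
            res = run_ga(matrix, labels, vocab, cfg)
            assert res.best[2] == 1.0
            assert "G01" in res.best[0].proteins

    def test_rules_deduplicated_and_sorted(self):
        matrix, labels = self._cohort()
        vocab = threshold_vocabulary(matrix, 3)
        cfg = GAConfig(population_size=40, survivors=10, generations=10, max_conditions=2, seed=1)
        res = run_ga(matrix, labels, vocab, cfg)
        keys = [r.canonical_key() for r, _, _ in res.rules]
        assert len(keys) == len(set(keys))
        scores = [f for _, _, f in res.rules]
        assert scores == sorted(scores, reverse=True)

    def test_single_class_cohort_rejected(self):
        matrix, _ = self._cohort()
        labels = [CourseLabel.FAVOURABLE] * matrix.shape[0]
        with pytest.raises(ValueError, match="each course group"):
            run_ga(matrix, labels, {"G01": [1.0]}, GAConfig(population_size=10, survivors=2))


class TestExhaustiveSearch:
    def test_tiny_instance_enumerable_by_hand(self):
        # one protein, one threshold: four rules; (G01<=1, favourable)
        # separates perfectly and wins the lexicographic tie with its
        # equally perfect complement formulation
        matrix = make_matrix([[0.5], [0.8], [1.5], [2.0]])
        labels = [CourseLabel.FAVOURABLE] * 2 + [CourseLabel.UNFAVOURABLE] * 2
        rule, score = exhaustive_search(matrix, labels, {"G01": [1.0]}, 1, FitnessSpec())
        assert score == 1.0
        assert rule.predicted_class is CourseLabel.FAVOURABLE
        assert rule.conditions == (Condition("G01", Comparator.LE, 1.0),)

    def test_matches_independent_enumeration(self):
        rng = np.random.default_rng(8)
        matrix = make_matrix(rng.lognormal(0, 0.4, (20, 3)))
        labels = [CourseLabel.UNFAVOURABLE if b else CourseLabel.FAVOURABLE
                  for b in rng.random(20) < 0.4]
        vocab = threshold_vocabulary(matrix, 3)
        rule, score = exhaustive_search(matrix, labels, vocab, 2, FitnessSpec())
        # oracle: enumerate condition satisfaction vectors directly
        sats = {}
        for pid, cuts in vocab.items():
            col = matrix.column(pid)
            for t in cuts:
                sats[(pid, "le", t)] = col <= t
                sats[(pid, "gt", t)] = col > t
        unfav = np.array([lab is CourseLabel.UNFAVOURABLE for lab in labels])
        scored = enumerate_rules_scores(sats, unfav, 2)
        # drop contradictory conjunctions (same protein, le t0 < gt t1 overlap empty)
        best_oracle = 0.0
        for (combo, _), s in scored:
            by_protein = {}
            ok = True
            for pid, comp, t in combo:
                lo, hi = by_protein.get(pid, (-np.inf, np.inf))
                if comp == "gt":
                    lo = max(lo, t)
                else:
                    hi = min(hi, t)
                if lo >= hi:
                    ok = False
                by_protein[pid] = (lo, hi)
            if ok:
                best_oracle = max(best_oracle, s)
        assert score == pytest.approx(best_oracle)

    def test_returned_score_dominates_all_rules(self, tiny_separable):
        matrix, labels = tiny_separable
        vocab = {"G01": [1.0, 1.5], "G02": [1.0]}
        rule, score = exhaustive_search(matrix, labels, vocab, 2, FitnessSpec())
        assert score == 1.0  # G01 <= 1.0 separates the classes perfectly

    def test_guard_on_search_space(self):
        matrix = make_matrix(np.arange(40.0).reshape(4, 10))
        labels = [CourseLabel.FAVOURABLE, CourseLabel.FAVOURABLE,
                  CourseLabel.UNFAVOURABLE, CourseLabel.UNFAVOURABLE]
        vocab = {f"G{j + 1:02d}": [1.0, 2.0, 3.0] for j in range(10)}
        with pytest.raises(ValueError, match="exceeds"):
            exhaustive_search(matrix, labels, vocab, 4, FitnessSpec())
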