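"""GA operators, annealing acceptance, and the full wrapper search."""

import numpy as np
import pytest

from fawfs.datatypes import mask_from_indices
from fawfs.wrapper_select import (
    FitnessEvaluator,
    GAConfig,
    GAState,
    crossover,
    fitness_from_accuracy,
    local_search,
    mutate,
    run_ga,
    sa_accept,
)


class ScriptedRng:
    """Minimal stand-in generator with scripted draw sequences."""

    def __init__(self, randoms=(), integers=(), choices=()):
        self._randoms = list(randoms)
        self._integers = list(integers)
        self._choices = list(choices)

    def random(self, *args):
        return self._randoms.pop(0)

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def choice(self, a, *args, **kwargs):
        return self._choices.pop(0)


class TestFitness:
    @pytest.mark.parametrize(
        "f_x,baseline,expected",
        [(0.8, 0.5, 0.3), (0.4, 0.5, 0.0), (0.5, 0.5, 0.0)],
    )
    def test_rectified_branches(self, f_x, baseline, expected):
        assert fitness_from_accuracy(f_x, baseline) == pytest.approx(expected)

    def test_baseline_defaults_to_majority_rate(self, small_dataset):
        ev = FitnessEvaluator(small_dataset, "knn")
        _, counts = np.unique(small_dataset.y, return_counts=True)
        assert ev.baseline == pytest.approx(counts.max() / counts.sum())

    def test_empty_mask_rejected(self, small_dataset):
        ev = FitnessEvaluator(small_dataset, "knn")
        with pytest.raises(ValueError):
            ev(np.zeros(small_dataset.n_features, dtype=bool))

    def test_cache_avoids_reevaluation(self, small_dataset):
        ev = FitnessEvaluator(small_dataset, "knn")
        mask = mask_from_indices([0, 1], small_dataset.n_features)
        ev(mask)
        n = ev.n_evaluations
        ev(mask.copy())
        assert ev.n_evaluations == n


class TestSaAccept:
    def test_improvement_always_accepted(self):
        accepted, p = sa_accept(0.5, 0.3, temperature=0.01)
        assert accepted and p == 1.0

    def test_tie_accepted(self):
        accepted, p = sa_accept(0.5, 0.5, temperature=1e-9)
        assert accepted and p == 1.0

    def test_worse_move_probability_closed_form(self):
        _, p = sa_accept(0.0, 0.1, temperature=0.1, energy_scale=1.0)
        assert p == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_infinite_temperature_limit(self):
        _, p = sa_accept(0.0, 0.5, temperature=1e9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            sa_accept(0.1, 0.2, temperature=0.0)

    def test_acceptance_law_monte_carlo(self):
        """Empirical acceptance of worse moves follows exp(-E*d/T)."""
        rng = np.random.default_rng(123)
        trials = 10_000
        accepts = sum(
            sa_accept(0.0, 0.1, 0.1, 1.0, rng)[0] for _ in range(trials)
        )
        p = np.exp(-1.0)
        sd = np.sqrt(p * (1 - p) / trials)
        assert abs(accepts / trials - p) <= 3 * sd


class TestOperators:
    def test_no_crossover_copies_parents(self):
        a = np.array([1, 1, 0], dtype=bool)
        b = np.array([0, 1, 1], dtype=bool)
        ca, cb = crossover(a, b, 0.0, ScriptedRng(randoms=[0.9]))
        np.testing.assert_array_equal(ca, a)
        np.testing.assert_array_equal(cb, b)

    def test_single_point_cut_and_empty_repair(self):
        a = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        b = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        rng = ScriptedRng(randoms=[0.0], integers=[3], choices=[2])
        ca, cb = crossover(a, b, 1.0, rng, union_idx=np.arange(6))
        np.testing.assert_array_equal(ca, np.ones(6, dtype=bool))
        # the all-zero child is repaired to exactly one active bit
        assert cb.sum() == 1 and cb[2]

    def test_crossover_identical_parents_closed(self):
        a = np.array([1, 0, 1, 0], dtype=bool)
        ca, cb = crossover(a, a, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(ca, a)
        np.testing.assert_array_equal(cb, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover(np.ones(3, bool), np.ones(4, bool), 1.0, np.random.default_rng(0))

    def test_mutation_zero_identity_and_full_flip(self):
        m = np.array([1, 0, 1, 1, 0], dtype=bool)
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(mutate(m, 0.0, rng), m)
        np.testing.assert_array_equal(mutate(m, 1.0, rng), ~m)

    def test_full_flip_of_all_ones_repaired(self):
        m = np.ones(5, dtype=bool)
        out = mutate(m, 1.0, np.random.default_rng(1))
        assert out.sum() == 1


class TestLocalSearch:
    def make_state(self, evaluator, masks, temperature):
        fits = [evaluator(m) for m in masks]
        best = int(np.argmax(fits))
        return GAState(
            population=[m.copy() for m in masks],
            fitness=list(fits),
            generation=0,
            temperature=temperature,
            best_mask=masks[best].copy(),
            best_fitness=fits[best],
        )

    def test_zero_iterations_is_identity(self, small_dataset):
        ev = FitnessEvaluator(small_dataset, "knn")
        union_idx = np.arange(small_dataset.n_features)
        masks = [mask_from_indices([0, 2], 10), mask_from_indices([1, 3, 5], 10)]
        state = self.make_state(ev, masks, 1.0)
        cfg = GAConfig(local_search_iters=0)
        out = local_search(state, ev, cfg, np.random.default_rng(0), union_idx)
        for before, after in zip(masks, out.population):
            np.testing.assert_array_equal(before, after)

    def test_greedy_limit_never_decreases_fitness(self, small_dataset):
        ev = FitnessEvaluator(small_dataset, "knn")
        union_idx = np.arange(small_dataset.n_features)
        masks = [mask_from_indices([0], 10), mask_from_indices([4, 7], 10)]
        state = self.make_state(ev, masks, 1e-12)
        before = list(state.fitness)
        cfg = GAConfig(local_search_iters=8)
        out = local_search(state, ev, cfg, np.random.default_rng(0), union_idx)
        for b, a in zip(before, out.fitness):
            assert a >= b - 1e-12


class TestRunGa:
    CFG = dict(population_size=8, n_generations=4, local_search_iters=2, seed=5)

    def test_zero_generations_returns_initial_best(self, small_dataset):
        union = np.ones(10, dtype=bool)
        cfg = GAConfig(population_size=8, n_generations=0, seed=5)
        best, history = run_ga(small_dataset, union, cfg, "knn")
        assert history.shape[0] == 1
        assert best.any()

    def test_best_fitness_nondecreasing(self, small_dataset):
        union = np.ones(10, dtype=bool)
        _, history = run_ga(small_dataset, union, GAConfig(**self.CFG), "knn")
        assert (np.diff(history["best_fitness"]) >= -1e-12).all()

    def test_temperature_schedule_geometric(self, small_dataset):
        union = np.ones(10, dtype=bool)
        cfg = GAConfig(**self.CFG)
        _, history = run_ga(small_dataset, union, cfg, "knn")
        gens = history["generation"].to_numpy()
        np.testing.assert_allclose(
            history["temperature"],
            cfg.initial_temperature * cfg.cooling_rate**gens,
            rtol=1e-12,
        )

    def test_seeded_determinism_bit_for_bit(self, small_dataset):
        union = np.ones(10, dtype=bool)
        cfg = GAConfig(**self.CFG)
        best1, hist1 = run_ga(small_dataset, union, cfg, "knn")
        best2, hist2 = run_ga(small_dataset, union, cfg, "knn")
        np.testing.assert_array_equal(best1, best2)
        assert hist1.equals(hist2)

    def test_search_restricted_to_union(self, small_dataset):
        union = mask_from_indices([1, 3, 5, 7, 9], 10)
        best, _ = run_ga(small_dataset, union, GAConfig(**self.CFG), "knn")
        assert best.any()
        assert not best[~union].any()

    def test_empty_union_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            run_ga(small_dataset, np.zeros(10, dtype=bool), GAConfig(**self.CFG), "knn")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(crossover_prob=1.5).validate()
        with pytest.raises(ValueError):
            GAConfig(cooling_rate=1.0).validate()
        with pytest.raises(ValueError):
            GAConfig(initial_temperature=0.0).validate()
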