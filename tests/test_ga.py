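"""Genetic algorithm operators: mutation, crossover, selection, adaptation, runs."""

import numpy as np
import pytest

from demogen_ga import (
    Bounds,
    DemographicModel,
    Dynamics,
    EngineConfig,
    Epoch,
    GAConfig,
    Individual,
    encode,
    expected_afs,
    model_loglikelihood,
    random_model,
    run_ga,
)
from demogen_ga.ga import (
    crossover,
    mutate,
    next_generation,
    select_parent,
    update_adaptive,
)
from demogen_ga.model import vector_spec


def make_individual(structure, rng, fitness=0.0):
    m = random_model(structure, Bounds(), rng)
    return Individual(m, fitness, np.ones(len(encode(m))))


class TestMutate:
    def test_number_mutated_follows_truncated_binomial(self, rng):
        """k = max(1, Binomial(N, strength)); for N = 5, p = 0.2 the exact
        mean is 1 + 0.8^5 = 1.32768 (the floor at one lifts the plain
        binomial mean of 1.0)."""
        from math import comb

        ind5 = make_individual((1, 1), rng)
        n = len(encode(ind5.model))
        ks = []
        for _ in range(4000):
            _, idx = mutate(ind5, rate=0.2, strength=0.2, rng=rng)
            ks.append(len(idx))
        exact = sum(max(1, k) * comb(n, k) * 0.2**k * 0.8 ** (n - k) for k in range(n + 1))
        se = np.std(ks) / np.sqrt(len(ks))
        assert abs(np.mean(ks) - exact) < 4 * se

    def test_dynamics_mutates_to_other_two_only(self, rng):
        m = DemographicModel((2,), [Epoch(0.5, (1.0,), (Dynamics.SUDDEN,))])
        ind = Individual(m, 0.0, np.ones(3))
        seen = set()
        for _ in range(200):
            child, idx = mutate(ind, 0.2, 0.9, rng)
            for e in child.epochs():
                seen.add(e.dynamics[0])
        assert Dynamics.SUDDEN in seen  # often unmutated
        assert seen - {Dynamics.SUDDEN} <= {Dynamics.LINEAR, Dynamics.EXPONENTIAL}

    def test_mutants_respect_bounds(self, rng):
        bounds = Bounds()
        spec = vector_spec((1, 1))
        ind = make_individual((1, 1), rng)
        for _ in range(300):
            child, _ = mutate(ind, 0.5, 0.5, rng, bounds)
            for slot, v in zip(spec, encode(child)):
                lo, hi = bounds.of_kind(slot.kind)
                assert lo <= v <= hi

    def test_invalid_rate_strength_rejected(self, rng):
        ind = make_individual((2,), rng)
        with pytest.raises(ValueError):
            mutate(ind, rate=0.2, strength=0.0, rng=rng)
        with pytest.raises(ValueError):
            mutate(ind, rate=-0.1, strength=0.2, rng=rng)


class TestCrossover:
    def test_identical_parents_give_identical_child(self, rng):
        a = make_individual((2, 1), rng)
        child = crossover(a, a, rng)
        np.testing.assert_array_equal(encode(child), encode(a.model))

    def test_child_parameters_come_from_parents(self, rng):
        a, b = make_individual((1, 1), rng), make_individual((1, 1), rng)
        va, vb = encode(a.model), encode(b.model)
        for _ in range(50):
            vc = encode(crossover(a, b, rng))
            assert all(c == x or c == y for c, x, y in zip(vc, va, vb))

    def test_per_position_frequency_near_half(self, rng):
        a, b = make_individual((1, 1), rng), make_individual((1, 1), rng)
        va, vb = encode(a.model), encode(b.model)
        differing = va != vb  # positions equal in both parents are uninformative
        n_trials = 2000
        from_a = np.zeros(len(va))
        for _ in range(n_trials):
            vc = encode(crossover(a, b, rng))
            from_a += vc == va
        freq = from_a[differing] / n_trials
        assert np.all(np.abs(freq - 0.5) < 4 * np.sqrt(0.25 / n_trials) + 1e-9)

    def test_structure_mismatch_rejected(self, rng):
        a, b = make_individual((1, 1), rng), make_individual((2, 1), rng)
        with pytest.raises(ValueError):
            crossover(a, b, rng)


class TestSelectParent:
    def test_equal_fitness_is_symmetric(self, rng):
        gen = [make_individual((2,), rng, fitness=-5.0) for _ in range(2)]
        picks = sum(select_parent(gen, rng) is gen[0] for _ in range(3000))
        assert abs(picks / 3000 - 0.5) < 0.05

    def test_best_selected_most_often(self, rng):
        gen = [make_individual((2,), rng, fitness=-float(i)) for i in range(10)]
        counts = np.zeros(10)
        for _ in range(4000):
            chosen = select_parent(gen, rng)
            counts[gen.index(chosen)] += 1
        # rank weights: best has weight 10/55, worst 1/55
        assert counts[0] == counts.max()
        assert counts[0] / 4000 == pytest.approx(10 / 55, abs=0.03)
        assert counts[-1] / 4000 == pytest.approx(1 / 55, abs=0.02)

    def test_single_individual_always_chosen(self, rng):
        gen = [make_individual((2,), rng)]
        assert select_parent(gen, rng) is gen[0]

    def test_all_neginf_falls_back_to_uniform(self, rng):
        gen = [make_individual((2,), rng, fitness=-np.inf) for _ in range(3)]
        assert select_parent(gen, rng) in gen


class TestAdaptive:
    def test_rate_multiplied_on_success(self):
        cfg = GAConfig(adaptive_const_rate=1.02)
        rate, _ = update_adaptive(0.2, 0.2, [True], [], cfg)
        assert rate == pytest.approx(0.204)

    def test_rate_divided_by_fourth_root_on_failure(self):
        cfg = GAConfig(adaptive_const_rate=1.02)
        rate, _ = update_adaptive(0.2, 0.2, [False], [], cfg)
        assert rate == pytest.approx(0.2 / 1.02**0.25)
        assert rate == pytest.approx(0.19901, abs=1e-5)

    def test_one_in_five_success_is_fixed_point(self):
        cfg = GAConfig(adaptive_const_rate=1.02)
        rate = 0.2
        rate, _ = update_adaptive(rate, 0.2, [True] + [False] * 4, [], cfg)
        assert rate == pytest.approx(0.2, rel=1e-12)

    def test_strength_requires_global_best(self):
        cfg = GAConfig(adaptive_const_strength=1.05)
        _, strength = update_adaptive(0.2, 0.2, [], [True], cfg)
        assert strength == pytest.approx(0.21)
        _, strength = update_adaptive(0.2, 0.2, [], [False], cfg)
        assert strength == pytest.approx(0.2 / 1.05**0.25)

    def test_constants_outside_unit_two_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(adaptive_const_rate=2.5)


class TestNextGeneration:
    def test_default_fractions_give_2_3_3_2(self):
        assert GAConfig().counts() == (2, 3, 3, 2)

    def test_elitism_keeps_best(self, rng):
        gen = [make_individual((2,), rng, fitness=float(-i)) for i in range(10)]
        new = next_generation(gen, GAConfig(), lambda m: -50.0, rng)
        assert len(new) == 10
        assert max(ind.fitness for ind in new) >= max(ind.fitness for ind in gen)

    def test_pure_elite_is_fixed_point(self, rng):
        cfg = GAConfig(fractions=(1.0, 0.0, 0.0, 0.0))
        gen = [make_individual((2,), rng, fitness=float(-i)) for i in range(10)]
        new = next_generation(gen, cfg, lambda m: 0.0, rng)
        old_vectors = sorted(tuple(encode(i.model)) for i in gen)
        new_vectors = sorted(tuple(encode(i.model)) for i in new)
        assert old_vectors == new_vectors

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GAConfig(fractions=(0.5, 0.5, 0.5, 0.5))


class TestRunGA:
    def _fitness_for(self, data, cfg):
        def fitness(m):
            try:
                return model_loglikelihood(m, data, cfg)[0]
            except Exception:
                return -np.inf
        return fitness

    @pytest.fixture(scope="class")
    def growth_problem(self):
        """Exact expected spectrum of a 1-population sudden expansion: the
        generating model attains the saturated composite likelihood."""
        true = DemographicModel((2,), [Epoch(0.3, (2.0,), (Dynamics.SUDDEN,))])
        cfg = EngineConfig(sample_sizes=(10,), theta0=500.0)
        data = expected_afs(true, cfg)
        return true, cfg, data

    def test_recovers_saturated_loglik(self, growth_problem):
        true, cfg, data = growth_problem
        fitness = self._fitness_for(data, cfg)
        target = fitness(true)
        best, _ = run_ga(
            fitness,
            (2,),
            GAConfig(stop_after_no_improvement=40, fixed_dynamics=Dynamics.SUDDEN),
            np.random.default_rng(4),
        )
        assert best.fitness >= target - 0.01

    def test_seed_reproducibility(self, growth_problem):
        _, cfg, data = growth_problem
        fitness = self._fitness_for(data, cfg)
        ga_cfg = GAConfig(stop_after_no_improvement=5)
        a, ha = run_ga(fitness, (2,), ga_cfg, np.random.default_rng(9))
        b, hb = run_ga(fitness, (2,), ga_cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(encode(a.model), encode(b.model))
        assert ha.best_ll == hb.best_ll

    def test_best_fitness_monotone_in_history(self, growth_problem):
        _, cfg, data = growth_problem
        fitness = self._fitness_for(data, cfg)
        _, hist = run_ga(
            fitness, (2,), GAConfig(stop_after_no_improvement=10), np.random.default_rng(2)
        )
        running = np.maximum.accumulate(hist.best_ll)
        np.testing.assert_array_equal(np.maximum.accumulate(running), running)

    def test_longer_patience_never_worse(self, growth_problem):
        _, cfg, data = growth_problem
        fitness = self._fitness_for(data, cfg)
        short, _ = run_ga(
            fitness, (2,), GAConfig(stop_after_no_improvement=5), np.random.default_rng(6)
        )
        long, _ = run_ga(
            fitness, (2,), GAConfig(stop_after_no_improvement=10), np.random.default_rng(6)
        )
        assert long.fitness >= short.fitness

    def test_initial_model_structure_checked(self, growth_problem, rng):
        _, cfg, data = growth_problem
        fitness = self._fitness_for(data, cfg)
        wrong = random_model((3,), Bounds(), rng)
        with pytest.raises(ValueError):
            run_ga(fitness, (2,), GAConfig(stop_after_no_improvement=2), rng, [wrong])
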