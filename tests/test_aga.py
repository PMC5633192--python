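"""Adaptive GA: operator schedules, selection, crossover, mutation, evolve."""

import numpy as np
import pytest

from welanopt.aga import (
    NARROW_BOUNDS,
    WIDE_BOUNDS,
    Bounds,
    GAConfig,
    crossover_pass,
    crossover_prob,
    evaluate_fitness,
    evolve,
    init_population,
    mutation_pass,
    mutation_prob,
    roulette_select,
    surrogate_fitness,
)
from welanopt.data_prep import CONDITION_COLUMNS, ScalingParams
from welanopt.svr import SVRConfig, fit

PRESETS = GAConfig()  # population 300, 500 generations, Pc 0.9/0.6, Pm 0.1/0.001


class TestSchedules:
    def test_crossover_prob_endpoints_and_midpoint(self):
        assert crossover_prob(0, PRESETS) == pytest.approx(0.9)
        # 0.9 * 2^-1 = 0.45 is floored at Pc_min
        assert crossover_prob(PRESETS.t_gen, PRESETS) == pytest.approx(0.6)
        assert crossover_prob(PRESETS.t_gen // 2, PRESETS) == pytest.approx(
            0.9 / np.sqrt(2), abs=1e-6
        )

    def test_crossover_prob_non_increasing_and_bounded(self):
        vals = [crossover_prob(t, PRESETS) for t in range(0, 501, 25)]
        assert np.all(np.diff(vals) <= 0)
        assert all(PRESETS.pc_min <= v <= PRESETS.pc_max for v in vals)

    def test_crossover_prob_floor_activates_late(self):
        # floor activates once 2^(-t/T) < Pc_min / Pc_max, i.e. t > 0.585 T
        t_cross = int(np.ceil(np.log2(0.9 / 0.6) * PRESETS.t_gen))
        assert crossover_prob(t_cross - 10, PRESETS) > PRESETS.pc_min
        assert crossover_prob(t_cross + 10, PRESETS) == PRESETS.pc_min

    def test_generation_out_of_range(self):
        with pytest.raises(ValueError):
            crossover_prob(-1, PRESETS)
        with pytest.raises(ValueError):
            crossover_prob(501, PRESETS)

    def test_mutation_prob_fittest_at_start(self):
        assert mutation_prob(2.5, 2.5, 0, PRESETS) == pytest.approx(0.1)

    def test_mutation_prob_worst_at_end(self):
        # exp(-1) * 1/2 * 0.1
        assert mutation_prob(0.0, 5.0, PRESETS.t_gen, PRESETS) == pytest.approx(
            np.exp(-1) * 0.05, abs=1e-9
        )

    def test_mutation_prob_floor(self, rng):
        for _ in range(200):
            f_max = float(rng.uniform(0.1, 50))
            f_i = float(rng.uniform(0, f_max))
            t = int(rng.integers(0, PRESETS.t_gen + 1))
            p = mutation_prob(f_i, f_max, t, PRESETS)
            assert PRESETS.pm_min <= p <= PRESETS.pm_max

    def test_mutation_prob_zero_fmax_warns_max_exploration(self):
        with pytest.warns(UserWarning):
            assert mutation_prob(0.0, 0.0, 3, PRESETS) == PRESETS.pm_max


class TestPopulation:
    def test_init_within_bounds_and_deterministic(self):
        pop = init_population(WIDE_BOUNDS, 100, rng=42)
        assert pop.shape == (100, 9)
        assert WIDE_BOUNDS.contains(pop)
        assert np.all(pop[:, 0] >= 5.0) and np.all(pop[:, 0] <= 95.0)
        assert np.array_equal(pop, init_population(WIDE_BOUNDS, 100, rng=42))

    def test_minimal_population(self):
        assert init_population(NARROW_BOUNDS, 2, rng=0).shape == (2, 9)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            Bounds(lo=(1,) * 9, hi=(1,) * 9)


class TestRoulette:
    def test_uniform_fitness_uniform_probabilities(self, rng):
        idx = roulette_select(np.ones(4), rng)
        assert idx.shape == (4,)
        assert set(idx) <= {0, 1, 2, 3}

    def test_empirical_frequencies_match_fitness_ratio(self):
        rng = np.random.default_rng(99)
        f = np.array([1.0, 3.0])
        draws = np.concatenate([roulette_select(f, rng) for _ in range(50_000)])
        freq1 = np.mean(draws == 1)
        assert freq1 == pytest.approx(0.75, abs=0.01)

    def test_single_positive_individual_always_selected(self, rng):
        idx = roulette_select(np.array([0.0, 0.0, 2.0]), rng)
        assert np.all(idx == 2)

    def test_zero_total_fitness_uniform_with_warning(self, rng):
        with pytest.warns(UserWarning):
            idx = roulette_select(np.zeros(5), rng)
        assert idx.shape == (5,)


class TestCrossover:
    def test_identical_individuals_unchanged(self, rng):
        pop = np.tile(np.arange(1.0, 10.0), (4, 1))
        out = crossover_pass(pop, 0, PRESETS, rng)
        assert np.array_equal(out, pop)

    def test_segment_swap_rule(self):
        """Adjacent pair swaps genes [start, end] inclusive (1-based)."""

        class FixedRng:
            def __init__(self):
                self.int_calls = 0

            def random(self):
                return 0.0  # always below Pc -> crossover happens

            def integers(self, lo, hi, size=None):
                return np.array([5, 2])  # unordered; smaller is the start

        A = np.arange(1.0, 10.0)
        B = np.arange(11.0, 20.0)
        out = crossover_pass(np.vstack([A, B]), 0, PRESETS, FixedRng())
        assert out[0].tolist() == [1, 12, 13, 14, 15, 6, 7, 8, 9]
        assert out[1].tolist() == [11, 2, 3, 4, 5, 16, 17, 18, 19]

    def test_pc_zero_leaves_population_unchanged(self, rng):
        cfg = GAConfig(pc_max=1e-9, pc_min=1e-9)
        pop = rng.random((10, 9))
        out = crossover_pass(pop, 0, cfg, np.random.default_rng(0))
        assert np.array_equal(out, pop)

    def test_positionwise_gene_multiset_conserved(self, rng):
        pop = rng.random((20, 9))
        out = crossover_pass(pop, 3, PRESETS, np.random.default_rng(7))
        for j in range(9):
            assert sorted(out[:, j]) == pytest.approx(sorted(pop[:, j]))

    def test_odd_population_last_individual_never_crosses_alone(self):
        pop = np.tile(np.arange(1.0, 10.0), (3, 1))
        pop[2] = 100.0
        out = crossover_pass(pop, 0, GAConfig(pc_max=1.0, pc_min=1.0),
                             np.random.default_rng(1))
        # first pair swaps (identical anyway); the third has no partner
        assert np.array_equal(out[2], pop[2])


class TestMutation:
    def test_pm_zero_unchanged(self, rng):
        cfg = GAConfig(pm_max=1e-12, pm_min=1e-12)
        pop = init_population(WIDE_BOUNDS, 10, rng=1)
        out, mask = mutation_pass(pop, np.ones(10), 0, cfg, WIDE_BOUNDS,
                                  np.random.default_rng(2))
        assert not mask.any() and np.array_equal(out, pop)

    def test_single_locus_and_within_bounds(self):
        cfg = GAConfig(pm_max=1.0, pm_min=1.0)  # force mutation
        rng = np.random.default_rng(3)
        pop = init_population(NARROW_BOUNDS, 200, rng=4)
        out, mask = mutation_pass(pop, np.ones(200), 0, cfg, NARROW_BOUNDS, rng)
        assert mask.all()
        assert NARROW_BOUNDS.contains(out)
        diffs = (out != pop).sum(axis=1)
        assert np.all(diffs <= 1)  # redrawing the same value is possible

    def test_mutated_genes_in_bounds_sweep(self):
        cfg = GAConfig(pm_max=1.0, pm_min=0.5)
        rng = np.random.default_rng(5)
        pop = init_population(WIDE_BOUNDS, 50, rng=6)
        fitness = np.linspace(1, 2, 50)
        for t in range(0, 201, 10):
            pop, _ = mutation_pass(pop, fitness, t, GAConfig(t_gen=500, pm_max=1.0,
                                   pm_min=0.5), WIDE_BOUNDS, rng)
            assert WIDE_BOUNDS.contains(pop)


class TestEvolve:
    @staticmethod
    def quad_fitness(G):
        x_star = NARROW_BOUNDS.lo_array + 0.5 * NARROW_BOUNDS.width
        w = 20.0 / NARROW_BOUNDS.width**2
        G = np.atleast_2d(G)
        return np.maximum(25.0 - np.sum(w * (G - x_star) ** 2, axis=1), 0.0)

    def test_t_gen_zero_returns_best_of_initial_population(self):
        cfg = GAConfig(pop_size=50, t_gen=0, seed=8)
        res = evolve(self.quad_fitness, NARROW_BOUNDS, cfg)
        pop = init_population(NARROW_BOUNDS, 50, rng=np.random.default_rng(8))
        f = self.quad_fitness(pop)
        assert res.best_fitness == pytest.approx(float(f.max()))
        assert len(res.best_trace) == 1

    def test_trace_length_and_elitism_monotonicity(self):
        cfg = GAConfig(pop_size=40, t_gen=60, seed=9, elitism=True)
        res = evolve(self.quad_fitness, NARROW_BOUNDS, cfg)
        assert len(res.best_trace) == cfg.t_gen + 1
        assert np.all(np.diff(res.best_trace) >= 0)
        assert res.best_fitness == pytest.approx(res.best_trace.max())

    def test_best_genes_feasible(self):
        res = evolve(self.quad_fitness, NARROW_BOUNDS,
                     GAConfig(pop_size=30, t_gen=30, seed=10))
        assert NARROW_BOUNDS.contains(res.best_genes)

    def test_reproducible_from_seed(self):
        cfg = GAConfig(pop_size=30, t_gen=25, seed=11)
        a = evolve(self.quad_fitness, NARROW_BOUNDS, cfg)
        b = evolve(self.quad_fitness, NARROW_BOUNDS, cfg)
        assert np.array_equal(a.best_genes, b.best_genes)
        assert np.array_equal(a.best_trace, b.best_trace)

    def test_converges_toward_known_optimum_reduced_scale(self):
        res = evolve(self.quad_fitness, NARROW_BOUNDS,
                     GAConfig(pop_size=100, t_gen=100, seed=12))
        x_star = NARROW_BOUNDS.lo_array + 0.5 * NARROW_BOUNDS.width
        err = np.abs(res.best_genes - x_star) / NARROW_BOUNDS.width
        assert np.all(err < 0.10)
        assert res.best_fitness > 24.5


class TestSurrogateFitness:
    def _toy_model(self, rng):
        """SVR trained on a bump in 9-D normalized space with scaling attached."""
        cols = list(CONDITION_COLUMNS) + ["production"]
        scaling = ScalingParams(
            x_min={c: float(lo) for c, lo in zip(cols, list(WIDE_BOUNDS.lo) + [0.0])},
            x_max={c: float(hi) for c, hi in zip(cols, list(WIDE_BOUNDS.hi) + [40.0])},
        )
        Z = rng.random((25, 9))
        y = np.exp(-np.sum((Z - 0.5) ** 2, axis=1))
        model = fit(Z, y, SVRConfig(C=10.0, epsilon=0.01, sigma=1.0), scaling=scaling)
        return model, scaling

    def test_constant_zero_model_maps_to_production_x_min(self, rng):
        model, scaling = self._toy_model(rng)
        model.coefficients = np.zeros_like(model.coefficients)
        model.bias = 0.0
        genes = WIDE_BOUNDS.lo_array + 0.3 * WIDE_BOUNDS.width
        assert evaluate_fitness(genes, model) == pytest.approx(
            scaling.x_min["production"]
        )

    def test_identical_candidates_identical_fitness(self, rng):
        model, _ = self._toy_model(rng)
        f = surrogate_fitness(model)
        genes = WIDE_BOUNDS.lo_array + 0.6 * WIDE_BOUNDS.width
        out = f(np.vstack([genes, genes]))
        assert out[0] == out[1]

    def test_fitness_never_negative(self, rng):
        model, _ = self._toy_model(rng)
        model.bias = -5.0  # force negative normalized predictions
        f = surrogate_fitness(model)
        pop = init_population(WIDE_BOUNDS, 50, rng=13)
        assert np.all(f(pop) >= 0.0)

    def test_candidate_at_free_sv_predicts_within_tube(self, rng):
        model, scaling = self._toy_model(rng)
        cfg = model.config
        thr = 1e-8 * cfg.C
        free = (np.abs(model.coefficients) > thr) & (
            np.abs(model.coefficients) < cfg.C - thr
        )
        assert free.any()
        z = model.support_vectors[np.flatnonzero(free)[0]]
        # denormalize the support vector back to raw genes
        lo = np.array([scaling.x_min[c] for c in CONDITION_COLUMNS])
        hi = np.array([scaling.x_max[c] for c in CONDITION_COLUMNS])
        genes = lo + z * (hi - lo)
        pred_norm = model.predict(z)
        got = evaluate_fitness(genes, model)
        span = scaling.x_max["production"] - scaling.x_min["production"]
        expected = scaling.x_min["production"] + pred_norm * span
        assert got == pytest.approx(max(expected, 0.0), abs=1e-9)
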