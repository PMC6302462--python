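import dataclasses
import itertools

import numpy as np
import pytest

from mwct.core import WeightTern, compute_mwct, compute_wct, repair_weights
from mwct.errors import ConfigError, ParameterError, StructuralInputError
from mwct.ga import (
    GAConfig,
    crossover_averaging,
    crossover_single_point,
    grid_search_oracle,
    init_population,
    mutate_permutation,
    run_ga,
    run_ga_windowed,
    select_parents,
)
from mwct.synth import generate_recording


class _FixedCutRng:
    """Duck-typed random source forcing the single-point cut position."""

    def __init__(self, cut):
        self._cut = cut

    def integers(self, *args, **kwargs):
        return self._cut


FAST_GA = dict(
    population_size=40, max_generations=80, convergence_window=15, seed=0
)


class TestGAConfig:
    def test_defaults_match_protocol(self):
        cfg = GAConfig()
        assert cfg.population_size == 80
        assert cfg.mutation_probability == 0.1

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(population_size=2),
            dict(mutation_probability=1.5),
            dict(elite_count=80),
            dict(max_generations=0),
            dict(crossover_single_point_share=-0.1),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            GAConfig(**kwargs)


class TestInitPopulation:
    def test_size_and_uniform_member(self, rng):
        population = init_population(GAConfig(), rng)
        assert len(population) == 80
        assert population.count(WeightTern.uniform()) == 1

    def test_all_valid(self, rng):
        for w in init_population(GAConfig(), rng):
            assert 0.0 < min(w) and max(w) < 1.0
            assert sum(w) == pytest.approx(1.0, abs=1e-9)


class TestCrossovers:
    def test_single_point_identical_parents(self, rng):
        p = WeightTern(0.2, 0.3, 0.5)
        c1, c2 = crossover_single_point(p, p, rng)
        assert (c1.alpha, c1.beta, c1.gamma) == pytest.approx(tuple(p), abs=1e-12)
        assert (c2.alpha, c2.beta, c2.gamma) == pytest.approx(tuple(p), abs=1e-12)

    def test_single_point_cut_after_gene_one(self):
        # oracle: hand renormalization of the raw child (0.2, 0.3, 0.2)
        p1 = WeightTern(0.2, 0.3, 0.5)
        p2 = WeightTern(0.5, 0.3, 0.2)
        c1, c2 = crossover_single_point(p1, p2, _FixedCutRng(1))
        assert tuple(c1) == pytest.approx((0.2 / 0.7, 0.3 / 0.7, 0.2 / 0.7))
        assert tuple(c2) == pytest.approx((0.5 / 1.3, 0.3 / 1.3, 0.5 / 1.3))

    def test_single_point_children_valid(self, rng):
        for _ in range(200):
            p1 = repair_weights(rng.dirichlet((1, 1, 1)))
            p2 = repair_weights(rng.dirichlet((1, 1, 1)))
            for c in crossover_single_point(p1, p2, rng):
                assert sum(c) == pytest.approx(1.0, abs=1e-9)

    def test_averaging_self(self):
        w = WeightTern(0.2, 0.3, 0.5)
        assert crossover_averaging(w, w) == w

    def test_averaging_midpoint(self):
        c = crossover_averaging(WeightTern(0.2, 0.3, 0.5), WeightTern(0.4, 0.5, 0.1))
        assert tuple(c) == pytest.approx((0.3, 0.4, 0.3))

    def test_averaging_preserves_sum(self, rng):
        p1 = repair_weights(rng.dirichlet((1, 1, 1)))
        p2 = repair_weights(rng.dirichlet((1, 1, 1)))
        c = crossover_averaging(p1, p2)
        assert sum(c) == pytest.approx((sum(p1) + sum(p2)) / 2, abs=1e-15)


class TestMutation:
    def test_uniform_tern_invariant(self, rng):
        w = WeightTern.uniform()
        for _ in range(20):
            assert mutate_permutation(w, 1.0, rng) == w

    def test_multiset_preserved(self, rng):
        w = WeightTern(0.2, 0.3, 0.5)
        for _ in range(100):
            out = mutate_permutation(w, 1.0, rng)
            assert sorted(out) == pytest.approx([0.2, 0.3, 0.5])

    def test_probability_zero_identity(self, rng):
        w = WeightTern(0.2, 0.3, 0.5)
        assert mutate_permutation(w, 0.0, rng) is w

    def test_mutation_is_non_identity_when_applied(self, rng):
        w = WeightTern(0.2, 0.3, 0.5)
        for _ in range(50):
            out = mutate_permutation(w, 1.0, rng)
            assert out != w

    def test_bad_probability(self, rng):
        with pytest.raises(ParameterError):
            mutate_permutation(WeightTern.uniform(), 1.5, rng)


class TestSelection:
    def test_empty_population(self, rng):
        with pytest.raises(StructuralInputError):
            select_parents([], [], rng)

    def test_single_member(self, rng):
        w = WeightTern(0.2, 0.3, 0.5)
        pairs = select_parents([w, w, w], [0.0, 0.0, 0.0], rng, n_pairs=5)
        assert all(p1 == w and p2 == w for p1, p2 in pairs)

    def test_best_selected_above_uniform_rate(self, rng):
        # oracle: P(best wins one tournament draw) = (1/N) * (2 - 1/N)
        n = 4
        population = [
            WeightTern(0.1, 0.2, 0.7),
            WeightTern(0.2, 0.3, 0.5),
            WeightTern(0.3, 0.3, 0.4),
            WeightTern(0.25, 0.25, 0.5),
        ]
        fitnesses = [0.1, 0.2, 0.3, 0.9]
        expected = (1 / n) * (2 - 1 / n)
        draws = 40_000
        pairs = select_parents(population, fitnesses, rng, n_pairs=draws)
        hits = sum(p is population[3] for pair in pairs for p in pair)
        assert hits / (2 * draws) == pytest.approx(expected, abs=0.01)
        assert expected > 1 / n

    def test_deterministic_under_seed(self):
        population = [WeightTern(0.2, 0.3, 0.5), WeightTern(0.5, 0.3, 0.2)]
        fitnesses = [0.1, 0.4]
        a = select_parents(population, fitnesses, np.random.default_rng(9), n_pairs=10)
        b = select_parents(population, fitnesses, np.random.default_rng(9), n_pairs=10)
        assert a == b


class TestRunGA:
    def test_never_worse_than_wct(self, noisy_params):
        rec, _ = generate_recording(noisy_params)
        result = run_ga(rec, GAConfig(**FAST_GA))
        assert np.mean(np.abs(result.mwct_trace.values)) <= np.mean(
            np.abs(compute_wct(rec).values)
        )

    def test_trajectory_non_decreasing(self, noisy_params):
        rec, _ = generate_recording(noisy_params)
        result = run_ga(rec, GAConfig(**FAST_GA))
        assert np.all(np.diff(result.fitness_trajectory) >= 0)
        assert result.generations_used <= 80
        assert result.generations_used == len(result.fitness_trajectory)

    def test_recovers_planted_tern(self, noisy_params):
        rec, planted = generate_recording(noisy_params)
        result = run_ga(rec, GAConfig(seed=11))
        err = np.max(np.abs(result.best_tern.as_array() - planted.as_array()))
        assert err <= 0.05

    def test_seed_determinism(self, noisy_params):
        rec, _ = generate_recording(noisy_params)
        cfg = GAConfig(**FAST_GA)
        a = run_ga(rec, cfg)
        b = run_ga(rec, cfg)
        assert a.best_tern == b.best_tern
        assert a.best_fitness == b.best_fitness
        np.testing.assert_array_equal(a.fitness_trajectory, b.fitness_trajectory)
        np.testing.assert_array_equal(a.mwct_trace.values, b.mwct_trace.values)

    def test_noise_free_reaches_floor_fitness(self, fast_params):
        # with the planted tern nulling the dipole exactly, the GA can reach
        # amplitudes at the fitness floor
        rec, planted = generate_recording(fast_params)
        result = run_ga(rec, GAConfig(seed=5))
        assert result.best_fitness > 1.0  # well below 1e-5 V


class TestRunGAWindowed:
    def test_single_window_equals_global(self, fast_params):
        rec, _ = generate_recording(fast_params)
        cfg = GAConfig(**FAST_GA)
        windowed = run_ga_windowed(rec, cfg, window_seconds=rec.duration)
        assert len(windowed.window_results) == 1
        sub = windowed.window_results[0]
        seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0])
        direct = run_ga(rec, dataclasses.replace(cfg, seed=seed))
        assert sub.best_tern == direct.best_tern

    def test_stationary_windows_agree(self, noisy_params):
        rec, _ = generate_recording(
            dataclasses.replace(noisy_params, duration=4.0)
        )
        windowed = run_ga_windowed(rec, GAConfig(seed=2), window_seconds=2.0)
        assert len(windowed.window_results) == 2
        t1 = windowed.window_results[0].best_tern.as_array()
        t2 = windowed.window_results[1].best_tern.as_array()
        assert np.max(np.abs(t1 - t2)) <= 0.05

    def test_average_tern_valid(self, noisy_params):
        rec, _ = generate_recording(dataclasses.replace(noisy_params, duration=4.0))
        windowed = run_ga_windowed(rec, GAConfig(**FAST_GA), window_seconds=1.0)
        avg = windowed.average_tern
        assert 0.0 < min(avg) and max(avg) < 1.0
        assert sum(avg) == pytest.approx(1.0, abs=1e-9)

    def test_window_too_long(self, fast_recording):
        rec, _ = fast_recording
        with pytest.raises(ParameterError):
            run_ga_windowed(rec, GAConfig(**FAST_GA), window_seconds=60.0)


class TestGridSearchOracle:
    def test_exact_recovery_on_grid(self, fast_params):
        rec, planted = generate_recording(fast_params)
        tern, amplitude = grid_search_oracle(rec, step=0.25)
        assert tern == planted  # (0.25, 0.25, 0.5) lies on the 0.25 lattice
        assert amplitude < 1e-15

    def test_matches_independent_enumeration(self, fast_recording):
        rec, _ = fast_recording
        step = 0.5
        # independent brute-force enumeration of the repaired lattice
        phi = np.stack([rec.phi_L, rec.phi_R, rec.phi_F])
        seen = {}
        for i, j in itertools.product(range(3), range(3)):
            gamma = 1.0 - (i + j) * step
            if gamma < -1e-12:
                continue
            t = repair_weights((i * step, j * step, gamma))
            seen[tuple(t)] = np.mean(np.abs(t.as_array() @ phi))
        expected_tern = min(seen, key=seen.get)
        tern, amplitude = grid_search_oracle(rec, step=step)
        assert tuple(tern) == expected_tern
        assert amplitude == pytest.approx(seen[expected_tern], rel=1e-12)

    def test_ga_matches_or_beats_lattice(self, noisy_params):
        rec, _ = generate_recording(noisy_params)
        _, oracle_amp = grid_search_oracle(rec, step=0.02)
        result = run_ga(rec, GAConfig(seed=3))
        ga_amp = np.mean(np.abs(result.mwct_trace.values))
        assert ga_amp <= oracle_amp * 1.05

    def test_bad_step(self, fast_recording):
        rec, _ = fast_recording
        with pytest.raises(ParameterError):
            grid_search_oracle(rec, step=0.6)
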