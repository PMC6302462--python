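"""Genetic algorithm over weight terns.

The population is a set of simplex points; the classic uniform-weight
chromosome is seeded into the initial population and re-inserted into every
generation, and elitism copies the fittest members forward unchanged, so the
best score can never fall below that of the plain averaged terminal.

A brute-force lattice search (:func:`grid_search_oracle`) is provided as an
independent verification oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_FITNESS_FLOOR,
    FITNESS_LOG_BASE,
    LimbPotentialRecording,
    PotentialTrace,
    WeightTern,
    compute_mwct,
    repair_weights,
)
from .errors import ConfigError, ParameterError, StructuralInputError

#: The five non-identity permutations of three gene positions.
_NON_IDENTITY_PERMS = ((0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the genetic minimization."""

    population_size: int = 80
    mutation_probability: float = 0.1
    elite_count: int = 2
    max_generations: int = 500
    convergence_window: int = 30
    convergence_tolerance: float = 1e-6
    crossover_single_point_share: float = 0.5
    seed: int = 0
    fitness_floor: float = DEFAULT_FITNESS_FLOOR

    def __post_init__(self) -> None:
        if self.population_size < 3:
            raise ConfigError(f"population_size must be >= 3, got {self.population_size}")
        if not (0.0 <= self.mutation_probability <= 1.0):
            raise ConfigError(
                f"mutation_probability must be in [0, 1], got {self.mutation_probability}"
            )
        if not (0 <= self.elite_count < self.population_size):
            raise ConfigError(
                f"elite_count must be in [0, population_size), got {self.elite_count}"
            )
        if self.max_generations < 1:
            raise ConfigError(f"max_generations must be >= 1, got {self.max_generations}")
        if self.convergence_window < 1:
            raise ConfigError(
                f"convergence_window must be >= 1, got {self.convergence_window}"
            )
        if not (0.0 <= self.crossover_single_point_share <= 1.0):
            raise ConfigError(
                "crossover_single_point_share must be in [0, 1], got "
                f"{self.crossover_single_point_share}"
            )
        if not (self.fitness_floor > 0):
            raise ConfigError(f"fitness_floor must be > 0, got {self.fitness_floor}")


@dataclass(frozen=True)
class GARunResult:
    """Outcome of one GA run on one recording (or window)."""

    best_tern: WeightTern
    best_fitness: float
    fitness_trajectory: np.ndarray
    generations_used: int
    mwct_trace: PotentialTrace
    mode: str = "global"


@dataclass(frozen=True)
class WindowedRunResult:
    """Per-window GA results plus the renormalized across-window mean tern."""

    window_results: tuple
    average_tern: WeightTern
    mode: str = field(default="windowed")


def init_population(cfg: GAConfig, rng: np.random.Generator) -> list[WeightTern]:
    """Initial population: one uniform chromosome, the rest uniform on the
    open simplex (flat Dirichlet, boundary-repaired)."""
    population = [WeightTern.uniform()]
    while len(population) < cfg.population_size:
        population.append(repair_weights(rng.dirichlet((1.0, 1.0, 1.0))))
    return population


def crossover_single_point(
    p1: WeightTern, p2: WeightTern, rng: np.random.Generator
) -> tuple[WeightTern, WeightTern]:
    """Swap gene tails at a uniformly drawn cut point and repair the sums."""
    cut = int(rng.integers(1, 3))  # after gene 1 or after gene 2
    a, b = p1.as_array(), p2.as_array()
    child1 = np.concatenate([a[:cut], b[cut:]])
    child2 = np.concatenate([b[:cut], a[cut:]])
    return repair_weights(child1), repair_weights(child2)


def crossover_averaging(p1: WeightTern, p2: WeightTern) -> WeightTern:
    """Component-wise midpoint; the midpoint of two simplex points stays on
    the simplex, so no repair is needed."""
    return WeightTern(
        0.5 * (p1.alpha + p2.alpha),
        0.5 * (p1.beta + p2.beta),
        0.5 * (p1.gamma + p2.gamma),
    )


def mutate_permutation(
    w: WeightTern, probability: float, rng: np.random.Generator
) -> WeightTern:
    """With the given probability, reorder the three weights by a uniformly
    drawn non-identity permutation.  The sum and open-interval constraints
    are preserved automatically."""
    if not (0.0 <= probability <= 1.0):
        raise ParameterError(f"mutation probability must be in [0, 1], got {probability}")
    if probability == 0.0 or rng.random() >= probability:
        return w
    perm = _NON_IDENTITY_PERMS[int(rng.integers(len(_NON_IDENTITY_PERMS)))]
    genes = (w.alpha, w.beta, w.gamma)
    return WeightTern(genes[perm[0]], genes[perm[1]], genes[perm[2]])


def _tournament_pick(population, fitnesses, rng: np.random.Generator):
    i, j = rng.integers(0, len(population), size=2)
    if fitnesses[i] > fitnesses[j]:
        return population[i]
    if fitnesses[j] > fitnesses[i]:
        return population[j]
    return population[i] if rng.random() < 0.5 else population[j]


def select_parents(
    population, fitnesses, rng: np.random.Generator, n_pairs: int = 1
) -> list[tuple[WeightTern, WeightTern]]:
    """Size-2 tournament selection: each parent is the fitter of two
    uniformly drawn individuals, ties broken uniformly at random."""
    if len(population) == 0:
        raise StructuralInputError("cannot select parents from an empty population")
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(fitnesses) != len(population):
        raise StructuralInputError("fitnesses and population lengths differ")
    if not np.all(np.isfinite(fitnesses)):
        raise StructuralInputError("fitnesses must be finite")
    return [
        (
            _tournament_pick(population, fitnesses, rng),
            _tournament_pick(population, fitnesses, rng),
        )
        for _ in range(n_pairs)
    ]


def _evaluate(population, phi: np.ndarray, floor: float) -> np.ndarray:
    """Vectorized fitness of a whole population on a stacked (3, n) signal."""
    weights = np.array([[w.alpha, w.beta, w.gamma] for w in population])
    amplitudes = np.abs(weights @ phi).mean(axis=1)
    return np.log(np.maximum(amplitudes, floor)) / np.log(FITNESS_LOG_BASE)


def run_ga(
    rec: LimbPotentialRecording, cfg: GAConfig, *, mode: str = "global"
) -> GARunResult:
    """Generational loop with elitism and uniform-chromosome preservation.

    Stops when the best fitness has improved by less than
    ``cfg.convergence_tolerance`` over ``cfg.convergence_window``
    consecutive generations, or at ``cfg.max_generations``.
    """
    rng = np.random.default_rng(cfg.seed)
    phi = np.stack([rec.phi_L, rec.phi_R, rec.phi_F])
    uniform = WeightTern.uniform()

    population = init_population(cfg, rng)
    best_tern = None
    best_fitness = -np.inf
    trajectory: list[float] = []

    for _generation in range(cfg.max_generations):
        fitnesses = _evaluate(population, phi, cfg.fitness_floor)
        top = int(np.argmax(fitnesses))
        if fitnesses[top] > best_fitness:
            best_fitness = float(fitnesses[top])
            best_tern = population[top]
        trajectory.append(best_fitness)

        window = cfg.convergence_window
        if (
            len(trajectory) > window
            and trajectory[-1] - trajectory[-1 - window] < cfg.convergence_tolerance
        ):
            break

        order = np.argsort(-fitnesses, kind="stable")
        next_population = [population[i] for i in order[: cfg.elite_count]]
        next_population.append(uniform)  # preserved in every generation
        while len(next_population) < cfg.population_size:
            (p1, p2), = select_parents(population, fitnesses, rng, 1)
            if rng.random() < cfg.crossover_single_point_share:
                offspring = list(crossover_single_point(p1, p2, rng))
            else:
                offspring = [crossover_averaging(p1, p2)]
            for child in offspring:
                if len(next_population) < cfg.population_size:
                    next_population.append(
                        mutate_permutation(child, cfg.mutation_probability, rng)
                    )
        population = next_population

    return GARunResult(
        best_tern=best_tern,
        best_fitness=best_fitness,
        fitness_trajectory=np.asarray(trajectory),
        generations_used=len(trajectory),
        mwct_trace=compute_mwct(rec, best_tern),
        mode=mode,
    )


def run_ga_windowed(
    rec: LimbPotentialRecording, cfg: GAConfig, window_seconds: float
) -> WindowedRunResult:
    """Run the GA independently on non-overlapping windows and report the
    renormalized across-window average of each weight."""
    if not (window_seconds > 0):
        raise ParameterError(f"window_seconds must be > 0, got {window_seconds}")
    samples_per_window = int(round(window_seconds * rec.sample_rate))
    if samples_per_window < 2:
        raise ParameterError("window too short for the sample rate")
    n_windows = rec.n_samples // samples_per_window
    if n_windows < 1:
        raise ParameterError(
            f"window of {window_seconds} s exceeds the {rec.duration} s recording"
        )
    window_seeds = np.random.SeedSequence(cfg.seed).generate_state(n_windows)
    results = []
    for k in range(n_windows):
        lo, hi = k * samples_per_window, (k + 1) * samples_per_window
        sub = LimbPotentialRecording(
            phi_L=rec.phi_L[lo:hi],
            phi_R=rec.phi_R[lo:hi],
            phi_F=rec.phi_F[lo:hi],
            sample_rate=rec.sample_rate,
            subject_id=rec.subject_id,
        )
        sub_cfg = dataclasses.replace(cfg, seed=int(window_seeds[k]))
        results.append(run_ga(sub, sub_cfg, mode="windowed"))
    mean_weights = np.mean([r.best_tern.as_array() for r in results], axis=0)
    return WindowedRunResult(
        window_results=tuple(results),
        average_tern=repair_weights(mean_weights),
    )


def grid_search_oracle(
    rec: LimbPotentialRecording, step: float
) -> tuple[WeightTern, float]:
    """Exhaustive lattice minimization of the mean absolute weighted mean.

    Lattice points ``(i*step, j*step, 1 - (i+j)*step)`` are projected onto
    the open simplex with :func:`mwct.core.repair_weights` and the
    mean-|trace| minimizer is returned together with its amplitude.
    Deterministic; intended as an independent check on the GA.
    """
    if not (0.0 < step <= 0.5):
        raise ParameterError(f"step must be in (0, 0.5], got {step}")
    phi = np.stack([rec.phi_L, rec.phi_R, rec.phi_F])
    n = int(np.floor(1.0 / step + 1e-12))
    candidates: dict[tuple[float, float, float], WeightTern] = {}
    for i in range(n + 1):
        for j in range(n + 1 - i):
            gamma = 1.0 - (i + j) * step
            if gamma < -1e-12:
                continue
            tern = repair_weights((i * step, j * step, gamma))
            candidates.setdefault((tern.alpha, tern.beta, tern.gamma), tern)
    terns = list(candidates.values())
    weights = np.array([[t.alpha, t.beta, t.gamma] for t in terns])
    amplitudes = np.abs(weights @ phi).mean(axis=1)
    best = int(np.argmin(amplitudes))
    return terns[best], float(amplitudes[best])
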