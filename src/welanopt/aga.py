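"""Adaptive genetic algorithm over bounded fermentation-condition space.

Real-coded GA on 9-gene chromosomes (the nine culture conditions in raw
units).  Selection is roulette (fitness-proportional); the crossover
probability decays with the generation counter,

    Pc(t) = max(Pc_max * 2^(-t / T_Gen), Pc_min),

and the mutation probability of an individual depends on both the generation
and its fitness gap to the population best,

    Pm(t, f_i) = max(exp(-|(f_max - f_i) / f_max|) * Pm_max / (1 + t / T_Gen),
                     Pm_min).

Crossover swaps a random inclusive gene segment between adjacent individuals;
mutation redraws one uniformly chosen gene inside its bound.  Fitness is the
surrogate's predicted production in g/L (clipped below at zero so roulette
weights stay non-negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data_prep import CONDITION_COLUMNS, PRODUCTION_COLUMN, denormalize_column
from .svr import SurrogateModel

__all__ = [
    "Bounds",
    "GAConfig",
    "GAResult",
    "WIDE_BOUNDS",
    "NARROW_BOUNDS",
    "init_population",
    "evaluate_fitness",
    "surrogate_fitness",
    "crossover_prob",
    "mutation_prob",
    "roulette_select",
    "crossover_pass",
    "mutation_pass",
    "evolve",
]

N_GENES = 9


@dataclass(frozen=True)
class Bounds:
    """Per-gene closed interval [lo_j, hi_j] in raw condition units."""

    lo: tuple[float, ...]
    hi: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lo) != N_GENES or len(self.hi) != N_GENES:
            raise ValueError(f"bounds must cover {N_GENES} genes")
        for j, (a, b) in enumerate(zip(self.lo, self.hi)):
            if not a < b:
                raise ValueError(f"gene {j + 1}: lower bound {a} must be < upper bound {b}")

    @property
    def lo_array(self) -> np.ndarray:
        return np.asarray(self.lo, dtype=float)

    @property
    def hi_array(self) -> np.ndarray:
        return np.asarray(self.hi, dtype=float)

    @property
    def width(self) -> np.ndarray:
        return self.hi_array - self.lo_array

    def contains(self, genes: np.ndarray) -> bool:
        g = np.atleast_2d(np.asarray(genes, dtype=float))
        return bool(np.all(g >= self.lo_array) and np.all(g <= self.hi_array))


#: Initial wide search box over the nine conditions.
WIDE_BOUNDS = Bounds(
    lo=(5.0, 1.0, 1.0, 0.1, 25.0, 2.0, 25.0, 125.0, 1.0),
    hi=(95.0, 10.0, 6.0, 1.0, 125.0, 12.0, 35.0, 250.0, 10.0),
)

#: Narrowed box around conditions of runs yielding above 30 g/L.
NARROW_BOUNDS = Bounds(
    lo=(55.0, 2.5, 5.0, 0.1, 48.0, 6.7, 32.0, 176.0, 4.85),
    hi=(60.0, 3.1, 5.5, 0.3, 51.5, 7.15, 33.0, 179.0, 5.15),
)

BOUND_PRESETS = {"wide": WIDE_BOUNDS, "narrow": NARROW_BOUNDS}


@dataclass(frozen=True)
class GAConfig:
    """GA settings; defaults are the study presets (population 300, 500
    iterations, Pc in [0.6, 0.9], Pm in [0.001, 0.1])."""

    pop_size: int = 300
    t_gen: int = 500
    pc_max: float = 0.9
    pc_min: float = 0.6
    pm_max: float = 0.1
    pm_min: float = 0.001
    seed: int = 0
    elitism: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError(f"population size must be >= 2, got {self.pop_size}")
        if self.t_gen < 0:
            raise ValueError(f"t_gen must be >= 0, got {self.t_gen}")
        if not 0 < self.pc_min <= self.pc_max <= 1:
            raise ValueError("require 0 < pc_min <= pc_max <= 1")
        if not 0 < self.pm_min <= self.pm_max <= 1:
            raise ValueError("require 0 < pm_min <= pm_max <= 1")


@dataclass
class GAResult:
    """Best individual found plus the per-generation fitness trace."""

    best_genes: np.ndarray
    best_fitness: float
    best_trace: np.ndarray  # length t_gen + 1, includes initial population
    mean_trace: np.ndarray
    seed: int
    config: GAConfig

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best_trace)),
                "best_fitness": self.best_trace,
                "mean_fitness": self.mean_trace,
            }
        )

    def best_conditions(self) -> dict[str, float]:
        return dict(zip(CONDITION_COLUMNS, map(float, self.best_genes)))


def crossover_prob(t: int, config: GAConfig) -> float:
    """Generation-dependent crossover probability, floored at Pc_min."""
    if not 0 <= t <= config.t_gen:
        raise ValueError(f"generation t={t} outside [0, {config.t_gen}]")
    t_gen = max(config.t_gen, 1)  # t_gen = 0 only with t = 0
    m_tmp = config.pc_max * 2.0 ** (-t / t_gen)
    return m_tmp if m_tmp > config.pc_min else config.pc_min


def _mutation_prob_vec(f: np.ndarray, f_max: float, t: int, config: GAConfig) -> np.ndarray:
    t_gen = max(config.t_gen, 1)
    if f_max == 0:
        warnings.warn("population max fitness is 0; using maximal mutation probability")
        return np.full(np.shape(f), config.pm_max)
    m_tmp = (
        np.exp(-np.abs((f_max - np.asarray(f, dtype=float)) / f_max))
        * (1.0 / (1.0 + t / t_gen))
        * config.pm_max
    )
    return np.where(m_tmp > config.pm_min, m_tmp, config.pm_min)


def mutation_prob(f_i: float, f_max: float, t: int, config: GAConfig) -> float:
    """Fitness- and generation-dependent mutation probability, floored at Pm_min."""
    if not 0 <= t <= config.t_gen:
        raise ValueError(f"generation t={t} outside [0, {config.t_gen}]")
    if f_max < f_i:
        raise ValueError(f"f_max ({f_max}) must be >= f_i ({f_i})")
    return float(_mutation_prob_vec(np.float64(f_i), f_max, t, config))


def init_population(bounds: Bounds, pop_size: int, rng: np.random.Generator | int) -> np.ndarray:
    """K individuals with genes uniform in their bounds."""
    if pop_size < 2:
        raise ValueError(f"population size must be >= 2, got {pop_size}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.uniform(bounds.lo_array, bounds.hi_array, size=(pop_size, N_GENES))


def surrogate_fitness(model: SurrogateModel) -> Callable[[np.ndarray], np.ndarray]:
    """Fitness function mapping raw-unit gene matrices to predicted g/L.

    Genes are normalized with the model's attached scaling, pushed through the
    kernel expansion, and the prediction denormalized back to g/L; negative
    predictions are floored at 0 so roulette weights stay valid.  Candidates
    outside the scaling's fitted range are still scaled (extrapolation).
    """
    if model.scaling is None:
        raise ValueError("surrogate model has no attached scaling parameters")
    scaling = model.scaling
    lo = np.array([scaling.x_min[c] for c in CONDITION_COLUMNS])
    hi = np.array([scaling.x_max[c] for c in CONDITION_COLUMNS])
    span = hi - lo

    def fitness(genes: np.ndarray) -> np.ndarray:
        G = np.atleast_2d(np.asarray(genes, dtype=float))
        Z = (scaling.y_max - scaling.y_min) * (G - lo) / span + scaling.y_min
        pred_norm = np.atleast_1d(model.predict(Z))
        pred = denormalize_column(pred_norm, scaling, PRODUCTION_COLUMN)
        return np.maximum(pred, 0.0)

    return fitness


def evaluate_fitness(genes: np.ndarray, model: SurrogateModel) -> float:
    """Predicted production (g/L) of one candidate condition vector."""
    return float(surrogate_fitness(model)(np.asarray(genes, dtype=float))[0])


def roulette_select(fitness: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """K fitness-proportional draws with replacement; returns selected indices."""
    f = np.asarray(fitness, dtype=float)
    if np.any(f < 0):
        raise ValueError("roulette selection requires non-negative fitness")
    total = f.sum()
    k = len(f)
    if total <= 0:
        warnings.warn("total fitness is 0; falling back to uniform selection")
        p = np.full(k, 1.0 / k)
    else:
        p = f / total
    return rng.choice(k, size=k, p=p)


def crossover_pass(
    genes: np.ndarray, t: int, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Segment crossover between adjacent individuals.

    Walks the population from the first individual; with probability Pc(t) the
    individual swaps an inclusive gene segment [start, end] (two random
    positions in 1..9, smaller = start) with the next adjacent individual,
    after which the walk advances by two, otherwise by one.  The final
    individual has no partner and never initiates a crossover.
    """
    out = np.array(genes, dtype=float, copy=True)
    pc = crossover_prob(t, config)
    k = len(out)
    i = 0
    while i < k - 1:
        if rng.random() < pc:
            a, b = rng.integers(1, N_GENES + 1, size=2)
            start, end = (a, b) if a <= b else (b, a)
            seg = slice(start - 1, end)  # 1-based inclusive -> python slice
            tmp = out[i, seg].copy()
            out[i, seg] = out[i + 1, seg]
            out[i + 1, seg] = tmp
            i += 2
        else:
            i += 1
    return out


def mutation_pass(
    genes: np.ndarray,
    fitness: np.ndarray,
    t: int,
    config: GAConfig,
    bounds: Bounds,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-locus mutation: per individual, with probability Pm(t, f_i) one
    uniformly chosen gene is redrawn uniformly within its bound.

    Returns (new genes, boolean mask of mutated individuals).
    """
    out = np.array(genes, dtype=float, copy=True)
    f = np.asarray(fitness, dtype=float)
    pm = _mutation_prob_vec(f, float(f.max()), t, config)
    mutated = rng.random(len(out)) < pm
    lo, hi = bounds.lo_array, bounds.hi_array
    for i in np.flatnonzero(mutated):
        j = int(rng.integers(0, N_GENES))
        out[i, j] = rng.uniform(lo[j], hi[j])
    return out, mutated


def evolve(
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    bounds: Bounds,
    config: GAConfig,
) -> GAResult:
    """Run the adaptive GA: select -> crossover -> mutate -> evaluate.

    ``fitness_fn`` maps a (K, 9) gene matrix to a length-K fitness vector in
    g/L (see :func:`surrogate_fitness`).  With elitism (default) the best
    individual found so far is copied into each new generation, making the
    per-generation best non-decreasing.  Fully reproducible from the config
    seed.
    """
    rng = np.random.default_rng(config.seed)
    genes = init_population(bounds, config.pop_size, rng)
    fit = np.asarray(fitness_fn(genes), dtype=float)

    best_idx = int(fit.argmax())
    best_genes = genes[best_idx].copy()
    best_fitness = float(fit[best_idx])
    best_trace = [float(fit.max())]
    mean_trace = [float(fit.mean())]

    for t in range(1, config.t_gen + 1):
        idx = roulette_select(fit, rng)
        genes, fit = genes[idx], fit[idx]
        genes = crossover_pass(genes, t, config, rng)
        fit = np.asarray(fitness_fn(genes), dtype=float)
        genes, mutated = mutation_pass(genes, fit, t, config, bounds, rng)
        if mutated.any():
            fit[mutated] = fitness_fn(genes[mutated])
        if config.elitism and fit.max() < best_fitness:
            worst = int(fit.argmin())
            genes[worst] = best_genes
            fit[worst] = best_fitness
        gen_best = int(fit.argmax())
        if fit[gen_best] > best_fitness:
            best_fitness = float(fit[gen_best])
            best_genes = genes[gen_best].copy()
        best_trace.append(float(fit.max()))
        mean_trace.append(float(fit.mean()))

    return GAResult(
        best_genes=best_genes,
        best_fitness=best_fitness,
        best_trace=np.asarray(best_trace),
        mean_trace=np.asarray(mean_trace),
        seed=config.seed,
        config=config,
    )
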