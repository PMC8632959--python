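"""Wrapper stage: genetic algorithm with simulated-annealing local search.

The search space is the set of non-empty feature masks contained in the
filter-stage union. Each individual is a boolean mask; its fitness is the
rectified excess of cross-validated accuracy f(x) over a baseline D
(default: the majority-class rate):

    Fit = f(x) - D   if f(x) > D,  else 0.

One generation = tournament selection, single-point crossover, per-bit
mutation, then a simulated-annealing local search: each individual
proposes single-bit flips that are accepted with probability 1 when the
flip does not increase the energy e = 1 - Fit, and with probability
exp(-E * d_e / T) otherwise, under a geometrically cooled temperature
T_g = T0 * cooling^g. Elitism carries the incumbent best forward, so the
best fitness is non-decreasing across generations. A fitness cache keyed
by the mask bits avoids re-training on repeated masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureMask, LabeledDataset
from .pipeline_eval import EvalProtocol, cross_validate

__all__ = [
    "GAConfig",
    "GAState",
    "FitnessEvaluator",
    "fitness",
    "sa_accept",
    "crossover",
    "mutate",
    "local_search",
    "run_ga",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the GA+SA wrapper.

    The temperature T0, cooling rate, and energy scale E govern the
    annealing acceptance; ``fitness_baseline`` is D (None = majority-class
    rate); ``patience`` terminates early when the best fitness has not
    improved for that many generations.
    """

    population_size: int = 30
    n_generations: int = 50
    local_search_iters: int = 10
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    initial_temperature: float = 1.0
    cooling_rate: float = 0.95
    energy_scale: float = 1.0
    elitism: int = 1
    patience: int = 10
    fitness_baseline: float | None = None
    n_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if not 0.0 < self.cooling_rate < 1.0:
            raise ValueError("cooling_rate must lie in (0, 1)")
        if self.energy_scale <= 0:
            raise ValueError("energy_scale must be positive")
        if not 1 <= self.elitism < self.population_size:
            raise ValueError("require 1 <= elitism < population_size")
        if self.local_search_iters < 0 or self.n_generations < 0:
            raise ValueError("iteration counts must be >= 0")


@dataclass
class GAState:
    """Evolving population state of the wrapper search."""

    population: list[FeatureMask]
    fitness: list[float]
    generation: int
    temperature: float
    best_mask: FeatureMask
    best_fitness: float


class FitnessEvaluator:
    """Cross-validated fitness with a cache keyed by the mask bits."""

    def __init__(
        self,
        dataset: LabeledDataset,
        classifier_name: str,
        n_folds: int = 5,
        baseline: float | None = None,
        seed: int = 0,
    ) -> None:
        self.dataset = dataset
        self.classifier_name = classifier_name
        self.protocol = EvalProtocol(n_folds=n_folds, seed=seed)
        if baseline is None:
            _, counts = np.unique(dataset.y, return_counts=True)
            baseline = float(counts.max() / counts.sum())
        self.baseline = baseline
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def accuracy(self, mask: FeatureMask) -> float:
        """Mean CV accuracy f(x) of the masked feature set (cached)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError("mask must select at least one feature")
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            self._cache[key] = cross_validate(
                self.dataset, mask, self.protocol, self.classifier_name
            ).mean_accuracy
            self.n_evaluations += 1
        return self._cache[key]

    def __call__(self, mask: FeatureMask) -> float:
        return fitness_from_accuracy(self.accuracy(mask), self.baseline)


def fitness_from_accuracy(f_x: float, baseline: float) -> float:
    """Rectified fitness: f(x) - D above the baseline, 0 at or below it."""
    return f_x - baseline if f_x > baseline else 0.0


def fitness(
    mask: FeatureMask,
    dataset: LabeledDataset,
    classifier_name: str,
    n_folds: int = 5,
    baseline: float | None = None,
    seed: int = 0,
) -> float:
    """Convenience one-shot fitness evaluation (no cache reuse)."""
    return FitnessEvaluator(dataset, classifier_name, n_folds, baseline, seed)(mask)


def sa_accept(
    e_current: float,
    e_candidate: float,
    temperature: float,
    energy_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[bool, float]:
    """Annealing acceptance of a candidate energy (minimization form).

    A candidate whose energy does not exceed the incumbent's is accepted
    with probability 1; a worse candidate with probability
    exp(-energy_scale * (e_candidate - e_current) / temperature).
    Returns ``(accepted, probability)``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    delta = e_candidate - e_current
    p = 1.0 if delta <= 0 else float(np.exp(-energy_scale * delta / temperature))
    if rng is None:
        rng = np.random.default_rng()
    return (p >= 1.0 or rng.random() < p), p


def _repair(mask: FeatureMask, union_idx: np.ndarray, rng: np.random.Generator) -> FeatureMask:
    """An all-zero mask is undefined; activate one random union bit."""
    if mask.any():
        return mask
    mask = mask.copy()
    mask[rng.choice(union_idx)] = True
    return mask


def crossover(
    parent_a: FeatureMask,
    parent_b: FeatureMask,
    crossover_prob: float,
    rng: np.random.Generator,
    union_idx: np.ndarray | None = None,
) -> tuple[FeatureMask, FeatureMask]:
    """Single-point crossover with probability ``crossover_prob``."""
    a = np.asarray(parent_a, dtype=bool)
    b = np.asarray(parent_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("parent masks must have equal length")
    if union_idx is None:
        union_idx = np.flatnonzero(a | b)
        if union_idx.size == 0:
            union_idx = np.arange(a.size)
    if rng.random() >= crossover_prob:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, a.size)) if a.size > 1 else 1
    child_a = np.concatenate([a[:cut], b[cut:]])
    child_b = np.concatenate([b[:cut], a[cut:]])
    return _repair(child_a, union_idx, rng), _repair(child_b, union_idx, rng)


def mutate(
    mask: FeatureMask,
    mutation_prob: float,
    rng: np.random.Generator,
    union_idx: np.ndarray | None = None,
) -> FeatureMask:
    """Flip each union bit independently with probability ``mutation_prob``."""
    mask = np.asarray(mask, dtype=bool).copy()
    if union_idx is None:
        union_idx = np.arange(mask.size)
    flips = rng.random(union_idx.size) < mutation_prob
    mask[union_idx[flips]] = ~mask[union_idx[flips]]
    return _repair(mask, union_idx, rng)


def local_search(
    state: GAState,
    evaluator: FitnessEvaluator,
    cfg: GAConfig,
    rng: np.random.Generator,
    union_idx: np.ndarray,
) -> GAState:
    """Simulated-annealing refinement of every individual in place.

    Each individual proposes ``local_search_iters`` single-bit flips;
    each proposal is kept or rejected by the annealing rule at the
    current temperature. At vanishing temperature only non-worsening
    flips survive, so fitness is then non-decreasing.
    """
    for i, mask in enumerate(state.population):
        current = mask
        e_current = 1.0 - state.fitness[i]
        for _ in range(cfg.local_search_iters):
            candidate = current.copy()
            bit = int(rng.choice(union_idx))
            candidate[bit] = ~candidate[bit]
            if not candidate.any():
                continue  # flipping the last active bit is not a valid move
            e_candidate = 1.0 - evaluator(candidate)
            accepted, _ = sa_accept(
                e_current, e_candidate, state.temperature, cfg.energy_scale, rng
            )
            if accepted:
                current, e_current = candidate, e_candidate
        state.population[i] = current
        state.fitness[i] = 1.0 - e_current
    return state


def _tournament(
    fitnesses: list[float], rng: np.random.Generator, size: int = 3
) -> int:
    contenders = rng.integers(0, len(fitnesses), size=size)
    return int(max(contenders, key=lambda i: fitnesses[i]))


def run_ga(
    dataset: LabeledDataset,
    union_mask: FeatureMask,
    cfg: GAConfig | None = None,
    classifier_name: str = "svm",
) -> tuple[FeatureMask, pd.DataFrame]:
    """Run the GA+SA wrapper inside the filter union.

    Returns the incumbent best mask and a per-generation history
    (best/mean fitness and temperature). Fully reproducible per seed:
    every stochastic choice is drawn from one seeded generator.
    """
    if cfg is None:
        cfg = GAConfig()
    cfg.validate()
    union_mask = np.asarray(union_mask, dtype=bool)
    union_idx = np.flatnonzero(union_mask)
    if union_idx.size < 1:
        raise ValueError("the filter union must contain at least one feature")

    rng = np.random.default_rng(cfg.seed)
    evaluator = FitnessEvaluator(
        dataset, classifier_name, cfg.n_folds, cfg.fitness_baseline, cfg.seed
    )

    # random initial population: each union bit on with probability 1/2
    population = []
    for _ in range(cfg.population_size):
        mask = np.zeros(union_mask.size, dtype=bool)
        mask[union_idx] = rng.random(union_idx.size) < 0.5
        population.append(_repair(mask, union_idx, rng))
    fitnesses = [evaluator(m) for m in population]

    best_i = int(np.argmax(fitnesses))
    state = GAState(
        population=population,
        fitness=fitnesses,
        generation=0,
        temperature=cfg.initial_temperature,
        best_mask=population[best_i].copy(),
        best_fitness=fitnesses[best_i],
    )

    history = [
        {
            "generation": 0,
            "best_fitness": state.best_fitness,
            "mean_fitness": float(np.mean(fitnesses)),
            "temperature": state.temperature,
        }
    ]
    stall = 0
    for gen in range(1, cfg.n_generations + 1):
        if stall >= cfg.patience:
            break
        # elites carried over: the all-time best plus the generation's best
        elite_order = np.argsort(state.fitness)[::-1][: cfg.elitism]
        elites = [(state.population[int(i)].copy(), state.fitness[int(i)])
                  for i in elite_order]
        elites[0] = (state.best_mask.copy(), state.best_fitness)
        # tournament selection of a mating pool
        parents = [
            state.population[_tournament(state.fitness, rng)]
            for _ in range(cfg.population_size)
        ]
        # crossover in adjacent pairs, then mutation
        children: list[FeatureMask] = []
        for j in range(0, cfg.population_size - 1, 2):
            c1, c2 = crossover(
                parents[j], parents[j + 1], cfg.crossover_prob, rng, union_idx
            )
            children.extend([c1, c2])
        if len(children) < cfg.population_size:  # odd population size
            children.append(parents[-1].copy())
        children = [
            mutate(c, cfg.mutation_prob, rng, union_idx) for c in children
        ]

        state.population = children
        state.fitness = [evaluator(c) for c in children]
        state.generation = gen
        state.temperature = cfg.initial_temperature * cfg.cooling_rate**gen
        state = local_search(state, evaluator, cfg, rng, union_idx)

        # elitism: the carried-over individuals replace the current worst
        order = np.argsort(state.fitness)
        for slot, (mask, fit) in zip(order[: cfg.elitism], elites):
            state.population[int(slot)] = mask
            state.fitness[int(slot)] = fit

        gen_best = int(np.argmax(state.fitness))
        if state.fitness[gen_best] > state.best_fitness:
            state.best_fitness = state.fitness[gen_best]
            state.best_mask = state.population[gen_best].copy()
            stall = 0
        else:
            stall += 1
        history.append(
            {
                "generation": gen,
                "best_fitness": state.best_fitness,
                "mean_fitness": float(np.mean(state.fitness)),
                "temperature": state.temperature,
            }
        )
    return state.best_mask, pd.DataFrame(history)
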