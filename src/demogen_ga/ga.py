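"""Genetic algorithm over demographic models of a fixed structure.

Individuals are demographic models sharing one structure; the fitness is
the Poisson composite log-likelihood (with the overall mutation scale
profiled out).  Generations are formed from elite copies, weighted
mutations, uniform crossovers and fresh random models; the mutation rate
and strength adapt by the one-fifth rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .model import (
    Bounds,
    DemographicModel,
    Dynamics,
    ParamSlot,
    clip_vector,
    decode,
    encode,
    random_model,
    vector_spec,
)

__all__ = [
    "GAConfig",
    "Individual",
    "mutate",
    "crossover",
    "select_parent",
    "next_generation",
    "update_adaptive",
    "run_ga",
    "GAHistory",
]

_DYN_CODES = (0.0, 1.0, 2.0)

#: floors/ceilings for the adaptive constants (documented clipping)
_RATE_RANGE = (1e-3, 2.0)
_STRENGTH_RANGE = (1e-2, 1.0)


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters.

    Defaults follow the settings used for the empirical analyses: ten
    models per generation split 0.2 : 0.3 : 0.3 : 0.2 into elite, mutated,
    crossed and random; mutation rate and strength 0.2 with adaptive
    constants 1.02 (rate) and 1.05 (strength); stop after 100 iterations
    without improvement of the log-likelihood rounded to 2 decimals.
    """

    generation_size: int = 10
    fractions: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)
    mutation_rate: float = 0.2
    mutation_strength: float = 0.2
    adaptive_const_strength: float = 1.05
    adaptive_const_rate: float = 1.02
    stop_after_no_improvement: int = 100
    ll_precision_decimals: int = 2
    bounds: Bounds = field(default_factory=Bounds)
    fixed_dynamics: Dynamics | None = None

    def __post_init__(self) -> None:
        if self.generation_size < 2:
            raise ValueError("generation size must be >= 2")
        if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
            raise ValueError("fractions must sum to 1")
        for c in (self.adaptive_const_strength, self.adaptive_const_rate):
            if not 1.0 <= c <= 2.0:
                raise ValueError("adaptive constants must lie in [1, 2]")

    def counts(self) -> tuple[int, int, int, int]:
        """Per-category counts: round(fraction * size), remainder to random."""
        n = self.generation_size
        n_best = round(self.fractions[0] * n)
        n_mut = round(self.fractions[1] * n)
        n_cross = round(self.fractions[2] * n)
        n_rand = n - n_best - n_mut - n_cross
        if n_rand < 0:
            raise ValueError("fractions incompatible with generation size")
        return n_best, n_mut, n_cross, n_rand


@dataclass
class Individual:
    """A model with its fitness and per-parameter mutation weights."""

    model: DemographicModel
    fitness: float
    weights: np.ndarray

    def copy(self) -> "Individual":
        return Individual(self.model.copy(), self.fitness, self.weights.copy())


FitnessFunc = Callable[[DemographicModel], float]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def mutate(
    ind: Individual,
    rate: float,
    strength: float,
    rng: np.random.Generator,
    bounds: Bounds | None = None,
    fixed_dynamics: bool = False,
) -> tuple[DemographicModel, np.ndarray]:
    """Mutate ``Binomial(N, strength)`` parameters (at least one).

    Parameters are picked with probability proportional to their weights.
    A numeric parameter ``theta`` becomes ``theta * (1 + s |x|)`` with the
    sign ``s`` equiprobable and ``x ~ Normal(rate, rate/2)`` (variance equal
    to half the mean); a dynamics parameter switches to one of the other
    two forms with equal probability.  Results are clipped into bounds.

    Returns the mutated model and the indices of mutated parameters.
    """
    if not 0.0 < strength <= 1.0 or rate <= 0.0:
        raise ValueError("require 0 < strength <= 1 and rate > 0")
    bounds = bounds or Bounds()
    spec = vector_spec(ind.model.structure)
    vec = encode(ind.model)
    n = len(vec)
    weights = np.asarray(ind.weights, dtype=float)
    if fixed_dynamics:
        eligible = np.array([s.kind != "dynamics" for s in spec], dtype=bool)
    else:
        eligible = np.ones(n, dtype=bool)
    if n == 0 or not eligible.any():  # nothing to mutate (parameter-free model)
        return ind.model.copy(), np.empty(0, dtype=int)
    k = max(1, rng.binomial(n, strength))
    k = min(k, int(eligible.sum()))
    probs = weights * eligible
    probs = probs / probs.sum()
    chosen = rng.choice(n, size=k, replace=False, p=probs)
    for i in chosen:
        slot = spec[i]
        if slot.kind == "dynamics":
            others = [c for c in _DYN_CODES if c != vec[i]]
            vec[i] = others[rng.integers(0, 2)]
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            x = abs(rng.normal(rate, math.sqrt(rate / 2.0)))
            vec[i] = vec[i] * (1.0 + sign * x)
    vec = clip_vector(vec, spec, bounds)
    return decode(vec, ind.model.structure), np.asarray(chosen)


def crossover(
    a: Individual, b: Individual, rng: np.random.Generator
) -> DemographicModel:
    """Uniform crossover: each child parameter comes from either parent
    with probability one half.  Structures must match."""
    if a.model.structure != b.model.structure:
        raise ValueError("cannot cross models of different structures")
    va, vb = encode(a.model), encode(b.model)
    pick = rng.random(len(va)) < 0.5
    return decode(np.where(pick, va, vb), a.model.structure)


def select_parent(
    generation: Sequence[Individual], rng: np.random.Generator
) -> Individual:
    """Rank-proportional selection: the better the fitness, the more likely.

    Weights are proportional to the fitness rank (best = highest weight),
    which preserves the required monotonicity while remaining well defined
    for arbitrarily shifted (negative) log-likelihoods.  If every fitness
    is ``-inf`` the choice is uniform.
    """
    if len(generation) == 0:
        raise ValueError("empty generation")
    fitnesses = np.array([ind.fitness for ind in generation])
    if np.all(np.isneginf(fitnesses)):
        weights = np.ones(len(generation))
    else:
        from scipy.stats import rankdata

        weights = rankdata(fitnesses, method="average")  # ties share their rank
    weights = weights / weights.sum()
    return generation[rng.choice(len(generation), p=weights)]


def update_adaptive(
    rate: float,
    strength: float,
    mutation_improved: Sequence[bool],
    mutation_new_best: Sequence[bool],
    config: GAConfig,
) -> tuple[float, float]:
    """One-fifth rule updates.

    For every mutation that improved on its parent the rate is multiplied
    by ``C_rate``, otherwise divided by ``C_rate ** (1/4)``; the strength is
    updated the same way with ``C_strength``, but success additionally
    requires the mutant to be a new global best.  Both are clipped to
    documented floors/ceilings.
    """
    c_r, c_s = config.adaptive_const_rate, config.adaptive_const_strength
    for ok in mutation_improved:
        rate = rate * c_r if ok else rate / c_r**0.25
    for ok in mutation_new_best:
        strength = strength * c_s if ok else strength / c_s**0.25
    rate = float(np.clip(rate, *_RATE_RANGE))
    strength = float(np.clip(strength, *_STRENGTH_RANGE))
    return rate, strength


# ---------------------------------------------------------------------------
# generation step
# ---------------------------------------------------------------------------

@dataclass
class _GAState:
    rate: float
    strength: float
    best: Individual


def next_generation(
    generation: list[Individual],
    config: GAConfig,
    fitness: FitnessFunc,
    rng: np.random.Generator,
    state: _GAState | None = None,
) -> list[Individual]:
    """Produce the next generation: elite, mutated, crossed, random.

    Elite individuals are copied unchanged, so the best-so-far fitness can
    never decrease.  If ``state`` is given, the adaptive rate/strength and
    the global best are updated in place.
    """
    n_best, n_mut, n_cross, n_rand = config.counts()
    rate = state.rate if state else config.mutation_rate
    strength = state.strength if state else config.mutation_strength
    structure = generation[0].model.structure
    n_params = len(encode(generation[0].model))

    ranked = sorted(generation, key=lambda ind: ind.fitness, reverse=True)
    new: list[Individual] = [ind.copy() for ind in ranked[:n_best]]

    improved_flags: list[bool] = []
    new_best_flags: list[bool] = []
    best_fit = state.best.fitness if state else ranked[0].fitness
    for _ in range(n_mut):
        parent = select_parent(generation, rng)
        child_model, mutated_idx = mutate(
            parent, rate, strength, rng, config.bounds, config.fixed_dynamics is not None
        )
        fit = fitness(child_model)
        weights = parent.weights.copy()
        improved = fit > parent.fitness
        if improved:
            # reward the parameters whose mutation helped
            weights[mutated_idx] += 1.0
        improved_flags.append(improved)
        new_best_flags.append(fit > best_fit)
        best_fit = max(best_fit, fit)
        new.append(Individual(child_model, fit, weights))
    for _ in range(n_cross):
        pa = select_parent(generation, rng)
        pb = select_parent(generation, rng)
        child_model = crossover(pa, pb, rng)
        new.append(Individual(child_model, fitness(child_model), np.ones(n_params)))
    for _ in range(n_rand):
        rm = random_model(structure, config.bounds, rng, config.fixed_dynamics)
        new.append(Individual(rm, fitness(rm), np.ones(n_params)))

    if state is not None:
        state.rate, state.strength = update_adaptive(
            state.rate, state.strength, improved_flags, new_best_flags, config
        )
        gen_best = max(new, key=lambda ind: ind.fitness)
        if gen_best.fitness > state.best.fitness:
            state.best = gen_best.copy()
    return new


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class GAHistory:
    """Per-iteration log: best/mean fitness and the adaptive constants."""

    best_ll: list[float] = field(default_factory=list)
    mean_ll: list[float] = field(default_factory=list)
    rate: list[float] = field(default_factory=list)
    strength: list[float] = field(default_factory=list)

    def append(self, gen: Sequence[Individual], rate: float, strength: float) -> None:
        fits = np.array([ind.fitness for ind in gen])
        finite = fits[np.isfinite(fits)]
        self.best_ll.append(float(fits.max()))
        self.mean_ll.append(float(finite.mean()) if finite.size else -np.inf)
        self.rate.append(rate)
        self.strength.append(strength)


def run_ga(
    fitness: FitnessFunc,
    structure: Sequence[int],
    config: GAConfig,
    rng: np.random.Generator,
    initial_models: Sequence[DemographicModel] | None = None,
) -> tuple[Individual, GAHistory]:
    """Run the GA until the rounded best log-likelihood stalls.

    The stopping rule follows the reference settings: the run ends after
    ``stop_after_no_improvement`` consecutive iterations without an
    improvement of the best fitness rounded to ``ll_precision_decimals``.
    Returns the best individual ever seen and the iteration history.
    """
    structure = tuple(structure)
    n_params = len(vector_spec(structure))
    generation: list[Individual] = []
    initial_models = list(initial_models or [])
    for m in initial_models[: config.generation_size]:
        if m.structure != structure:
            raise ValueError("initial model structure does not match the run structure")
        generation.append(Individual(m, fitness(m), np.ones(n_params)))
    while len(generation) < config.generation_size:
        m = random_model(structure, config.bounds, rng, config.fixed_dynamics)
        generation.append(Individual(m, fitness(m), np.ones(n_params)))

    state = _GAState(
        rate=config.mutation_rate,
        strength=config.mutation_strength,
        best=max(generation, key=lambda i: i.fitness).copy(),
    )
    history = GAHistory()
    history.append(generation, state.rate, state.strength)

    stale = 0
    best_rounded = round(state.best.fitness, config.ll_precision_decimals)
    while stale < config.stop_after_no_improvement:
        generation = next_generation(generation, config, fitness, rng, state)
        history.append(generation, state.rate, state.strength)
        rounded = round(state.best.fitness, config.ll_precision_decimals)
        if rounded > best_rounded:
            best_rounded = rounded
            stale = 0
        else:
            stale += 1
    return state.best, history
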