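"""Artificial-bee-colony generation step.

One generation runs the three classical phases over a subpopulation whose
first ``floor(size * food_source_fraction)`` members are the food sources:

* employed phase — each food source i is perturbed toward/away from a random
  other source k, v = x_i + phi (x_i - x_k), with a single scalar
  phi ~ U(phi_range) applied to every gene, then repaired and greedily
  compared (candidate kept on ties);
* onlooker phase — each remaining member picks a food source with
  probability proportional to a positive selection fitness
  F_i = 1/(1+E_i) for E_i >= 0 else 1 + |E_i| (energies can be negative, so
  the raw energy cannot be used as a sampling weight) and perturbs it the
  same way;
* scout phase — at most one food source whose failure counter exceeds
  ``limit`` (the worst-energy such source) is abandoned and replaced by a
  fresh random genotype.

Energy is the fitness and is minimized throughout.  Every candidate
evaluation counts against the caller's budget; the generation truncates
cleanly when the budget runs out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FoodSource",
    "AbcConfig",
    "neighbor_candidate",
    "greedy_select",
    "selection_probabilities",
    "abc_generation",
    "evolution_rate",
]

EPS_RATE = 1e-12  # floor for the evolution rate (keeps the partition update defined)


@dataclass
class FoodSource:
    """One individual: raw gene vector, cached energy, failure counter."""

    vector: np.ndarray
    energy: float = np.inf
    trials: int = 0

    def copy(self) -> "FoodSource":
        return FoodSource(self.vector.copy(), self.energy, self.trials)


@dataclass
class AbcConfig:
    limit: int = 100
    phi_range: tuple[float, float] = (-1.0, 1.0)
    food_source_fraction: float = 0.5
    per_gene_phi: bool = False

    def __post_init__(self) -> None:
        if self.limit < 1:
            raise ValueError("limit must be >= 1")
        lo, hi = self.phi_range
        if not np.isclose(lo, -hi):
            raise ValueError("phi_range must be symmetric about 0")


def neighbor_candidate(x_i: np.ndarray, x_k: np.ndarray,
                       rng: np.random.Generator,
                       repair: Callable[[np.ndarray], np.ndarray],
                       phi_range: tuple[float, float] = (-1.0, 1.0),
                       per_gene: bool = False) -> np.ndarray:
    """v = x_i + phi (x_i - x_k) on the raw gene vector, then repaired."""
    if x_i is x_k:
        raise ValueError("neighbor must differ from the perturbed source")
    if per_gene:
        phi = rng.uniform(phi_range[0], phi_range[1], size=len(x_i))
    else:
        phi = rng.uniform(phi_range[0], phi_range[1])
    return repair(x_i + phi * (x_i - x_k))


def greedy_select(current: FoodSource, candidate_vector: np.ndarray,
                  candidate_energy: float) -> FoodSource:
    """Keep the candidate iff its energy is <= the current energy (ties go
    to the candidate); replacement resets the failure counter, otherwise it
    increments."""
    if candidate_energy <= current.energy:
        return FoodSource(candidate_vector, candidate_energy, trials=0)
    current.trials += 1
    return current


def selection_probabilities(energies: Sequence[float]) -> np.ndarray:
    """Onlooker selection distribution over food sources.

    Lower energy => strictly higher probability; always a valid
    distribution.  Uses the standard positive transform
    F = 1/(1+E) for E >= 0, 1+|E| otherwise."""
    e = np.asarray(energies, float)
    if e.size == 0:
        raise ValueError("no food sources")
    fitness = np.empty_like(e)
    pos = e >= 0
    fitness[pos] = 1.0 / (1.0 + e[pos])
    fitness[~pos] = 1.0 + np.abs(e[~pos])
    return fitness / fitness.sum()


def evolution_rate(energies_before: Sequence[float],
                   energies_after: Sequence[float],
                   eps_denom: float = 1e-12) -> float:
    """Per-slot relative improvement summed over the subpopulation,
    floored at EPS_RATE so downstream ratios stay defined.  Improvement
    (energy decrease) contributes positively."""
    before = np.asarray(energies_before, float)
    after = np.asarray(energies_after, float)
    if before.shape != after.shape:
        raise ValueError("before/after energy vectors must pair up by slot")
    v = float(np.sum((before - after) / (np.abs(after) + eps_denom)))
    return max(EPS_RATE, v)


def abc_generation(subpop: list[FoodSource],
                   score_fn: Callable[[np.ndarray], float],
                   repair: Callable[[np.ndarray], np.ndarray],
                   sampler: Callable[[np.random.Generator], np.ndarray],
                   config: AbcConfig,
                   rng: np.random.Generator,
                   budget: int) -> tuple[list[FoodSource], int, float]:
    """Evolve ``subpop`` for one ABC generation.

    Returns (new subpopulation, evaluations used, evolution rate).  The
    evolution rate is measured on the food-source slots across the employed
    and onlooker phases, before any scout restart (a restart is a deliberate
    diversification, not search progress)."""
    if len(subpop) < 4:
        raise ValueError("ABC requires a subpopulation of at least 4")
    pop = [fs for fs in subpop]
    n_food = max(2, int(len(pop) * config.food_source_fraction))
    used = 0

    before = [pop[i].energy for i in range(n_food)]

    # employed phase
    for i in range(n_food):
        if used >= budget:
            break
        k = int(rng.integers(n_food - 1))
        if k >= i:
            k += 1
        v = neighbor_candidate(pop[i].vector, pop[k].vector, rng, repair,
                               config.phi_range, config.per_gene_phi)
        e = score_fn(v)
        used += 1
        pop[i] = greedy_select(pop[i], v, e)

    # onlooker phase
    n_onlookers = len(pop) - n_food
    for _ in range(n_onlookers):
        if used >= budget:
            break
        probs = selection_probabilities([pop[i].energy for i in range(n_food)])
        i = int(rng.choice(n_food, p=probs))
        k = int(rng.integers(n_food - 1))
        if k >= i:
            k += 1
        v = neighbor_candidate(pop[i].vector, pop[k].vector, rng, repair,
                               config.phi_range, config.per_gene_phi)
        e = score_fn(v)
        used += 1
        pop[i] = greedy_select(pop[i], v, e)

    after = [pop[i].energy for i in range(n_food)]
    rate = evolution_rate(before, after)

    # scout phase: at most one stagnated source (the worst such) restarts
    if used < budget:
        stale = [i for i in range(n_food) if pop[i].trials > config.limit]
        if stale:
            worst = max(stale, key=lambda i: pop[i].energy)
            v = repair(sampler(rng))
            e = score_fn(v)
            used += 1
            pop[worst] = FoodSource(v, e, trials=0)

    return pop, used, rate
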