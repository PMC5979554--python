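"""Differential-evolution generation step (rand/1/bin).

For each target x_i a mutant is formed from three distinct random donors,
v = x_r1 + F (x_r2 - x_r3), crossed over binomially at rate CR with one
uniformly chosen gene forced to come from the mutant (without the forced
gene the trial can equal the target and the search stalls), repaired, and
then survives one-to-one against the target when its energy is <= the
target's.  Per-slot energies are therefore non-increasing within a
generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .abc_engine import FoodSource, evolution_rate

__all__ = ["DeConfig", "mutate", "crossover", "de_select", "de_generation"]


@dataclass
class DeConfig:
    F: float = 0.90   # differential weight
    CR: float = 0.80  # crossover probability

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be positive")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must lie in [0, 1]")


def mutate(x_r1: np.ndarray, x_r2: np.ndarray, x_r3: np.ndarray, F: float,
           repair: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """v = x_r1 + F (x_r2 - x_r3) on the raw gene vector, then repaired."""
    if x_r1 is x_r2 or x_r1 is x_r3 or x_r2 is x_r3:
        raise ValueError("donor indices must be pairwise distinct")
    return repair(x_r1 + F * (x_r2 - x_r3))


def crossover(target: np.ndarray, mutant: np.ndarray, CR: float,
              rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover: gene d comes from the mutant when
    rand(0,1) < CR; one uniformly chosen gene (j_rand) always comes from
    the mutant."""
    if target.shape != mutant.shape:
        raise ValueError("target and mutant must share dimensionality")
    take = rng.random(len(target)) < CR
    take[int(rng.integers(len(target)))] = True
    return np.where(take, mutant, target)


def de_select(target_energy: float, trial_energy: float) -> bool:
    """True when the trial survives (trial_energy <= target_energy)."""
    return trial_energy <= target_energy


def de_generation(subpop: list[FoodSource],
                  score_fn: Callable[[np.ndarray], float],
                  repair: Callable[[np.ndarray], np.ndarray],
                  config: DeConfig,
                  rng: np.random.Generator,
                  budget: int) -> tuple[list[FoodSource], int, float]:
    """Evolve ``subpop`` for one DE generation.

    Returns (new subpopulation, evaluations used, evolution rate).  Each
    individual serves once as the target; donors are drawn uniformly without
    replacement from the subpopulation excluding the target.  Truncates
    cleanly when the budget runs out."""
    if len(subpop) < 4:
        raise ValueError("DE requires at least 4 individuals")
    pop = [fs for fs in subpop]
    n = len(pop)
    used = 0
    before = [fs.energy for fs in pop]

    for i in range(n):
        if used >= budget:
            break
        donors = rng.choice(n - 1, size=3, replace=False)
        donors = [int(d) if d < i else int(d) + 1 for d in donors]
        r1, r2, r3 = donors
        v = mutate(pop[r1].vector, pop[r2].vector, pop[r3].vector,
                   config.F, repair)
        u = repair(crossover(pop[i].vector, v, config.CR, rng))
        e = score_fn(u)
        used += 1
        if de_select(pop[i].energy, e):
            pop[i] = FoodSource(u, e, trials=0)
        else:
            pop[i].trials += 1

    rate = evolution_rate(before, [fs.energy for fs in pop])
    return pop, used, rate
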