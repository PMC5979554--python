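"""Adaptive-population-partition (APP) hybrid driver.

Every generation the population of M individuals is shuffled and split into
two subpopulations of sizes M1 = round(M * PR) and M2 = M - M1 (both held at
>= 4 so each engine stays defined).  Subpopulation 1 evolves by one
artificial-bee-colony generation, subpopulation 2 by one differential-
evolution generation.  After merging, the E = round(elite_fraction * M)
lowest-energy individuals are flagged as elites and each engine's share of
them (the elite probability O_z = E_z / M_z) is combined with its evolution
rate v_z to update the partition rate:

    PR = O1 v1 / (O1 v1 + O2 v2),   clamped to [PR_min, PR_max].

A zero denominator — and the case where neither engine improved anything,
i.e. both rates sit at the numerical floor — falls back to PR = 0.5.
Termination is by a score-function evaluation budget.

The driver is generic over a :class:`Problem` (score / repair / sample), so
the same machinery optimizes analytic benchmark landscapes and docking
energy models; :func:`run_adhdock` and :func:`run_baseline` wrap it for
receptor/ligand inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .abc_engine import EPS_RATE, AbcConfig, FoodSource, abc_generation
from .conformation import Genotype, Pose, SearchBox, build_pose, random_genotype, \
    repair_vector
from .de_engine import DeConfig, de_generation
from .model_io import ForceFieldTable, Ligand, Receptor, load_forcefield
from .scoring import EnergyBreakdown, EnergyModel

__all__ = [
    "Problem",
    "DockingProblem",
    "RunConfig",
    "GenerationRecord",
    "OptResult",
    "DockResult",
    "partition_population",
    "find_elites",
    "elite_probability",
    "update_partition_rate",
    "optimize",
    "run_adhdock",
    "run_baseline",
]

PR_BOUNDS_DEFAULT = (0.1, 0.9)
MIN_SUBPOP = 4


class Problem(Protocol):
    """What the optimizers need from an objective."""

    def score(self, vector: np.ndarray) -> float: ...
    def repair(self, vector: np.ndarray) -> np.ndarray: ...
    def sample(self, rng: np.random.Generator) -> np.ndarray: ...


class DockingProblem:
    """Binding-energy objective over genotype vectors for one complex."""

    def __init__(self, receptor: Receptor, ligand: Ligand, box: SearchBox,
                 table: ForceFieldTable | None = None,
                 cutoff: float | None = None) -> None:
        self.table = table if table is not None else load_forcefield("ad4")
        self.box = box
        self.ligand = ligand
        self.model = EnergyModel(receptor, ligand, self.table, cutoff=cutoff)

    def score(self, vector: np.ndarray) -> float:
        return self.model.score_vector(vector, self.box)

    def repair(self, vector: np.ndarray) -> np.ndarray:
        return repair_vector(vector, self.box)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return random_genotype(self.ligand.n_torsions, self.box, rng).to_vector()

    def genotype(self, vector: np.ndarray) -> Genotype:
        return Genotype.from_vector(vector, self.ligand.n_torsions)

    def pose(self, vector: np.ndarray) -> Pose:
        return build_pose(self.ligand, self.genotype(vector), self.box)

    def breakdown(self, vector: np.ndarray) -> EnergyBreakdown:
        return self.model.breakdown(self.genotype(vector), self.box)


@dataclass
class RunConfig:
    """Run parameters.  Defaults follow the reference protocol: 100
    individuals, a 27,000-evaluation budget, initial partition rate 0.5,
    20% elites, ABC limit 100 with 50 food sources at M = 100, DE with
    F = 0.9 and CR = 0.8."""

    population: int = 100
    budget: int = 27000
    pr_init: float = 0.5
    pr_bounds: tuple[float, float] = PR_BOUNDS_DEFAULT
    elite_fraction: float = 0.2
    seed: int = 0
    abc: AbcConfig = field(default_factory=AbcConfig)
    de: DeConfig = field(default_factory=DeConfig)
    trace_every: int = 1

    def __post_init__(self) -> None:
        if self.population < 2 * MIN_SUBPOP:
            raise ValueError(f"population must be >= {2 * MIN_SUBPOP}")
        if self.budget < self.population:
            raise ValueError("budget must cover at least the initial evaluation")


@dataclass
class GenerationRecord:
    generation: int
    evaluations: int
    best_energy: float
    pr: float
    m1: int
    m2: int
    o1: float
    o2: float
    v1: float
    v2: float


@dataclass
class OptResult:
    best_vector: np.ndarray
    best_energy: float
    evaluations: int
    trace: list[GenerationRecord]

    @property
    def convergence(self) -> list[tuple[int, float]]:
        return [(r.evaluations, r.best_energy) for r in self.trace]


@dataclass
class DockResult:
    genotype: Genotype
    energy: float
    breakdown: EnergyBreakdown
    pose: Pose
    evaluations: int
    trace: list[GenerationRecord]

    @property
    def convergence(self) -> list[tuple[int, float]]:
        return [(r.evaluations, r.best_energy) for r in self.trace]


# --------------------------------------------------------------------------
# APP primitives

def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def partition_population(population: list[FoodSource], pr: float,
                         rng: np.random.Generator,
                         min_size: int = MIN_SUBPOP
                         ) -> tuple[list[FoodSource], list[FoodSource]]:
    """Shuffle and split: first round(M * PR) individuals to the ABC
    subpopulation, rest to DE, both sizes forced to >= min_size.  No
    individual is duplicated or dropped."""
    m = len(population)
    if m < 2 * min_size:
        raise ValueError(f"population must have at least {2 * min_size} members")
    m1 = _round_half_away(m * pr)
    m1 = min(max(m1, min_size), m - min_size)
    order = rng.permutation(m)
    sub1 = [population[i] for i in order[:m1]]
    sub2 = [population[i] for i in order[m1:]]
    return sub1, sub2


def find_elites(energies: np.ndarray, elite_fraction: float) -> np.ndarray:
    """Boolean flags for the E = round(fraction * M) lowest-energy
    individuals; ties at the boundary break by stable population order."""
    energies = np.asarray(energies, float)
    m = len(energies)
    e = _round_half_away(elite_fraction * m)
    flags = np.zeros(m, dtype=bool)
    if e > 0:
        order = np.argsort(energies, kind="stable")
        flags[order[:e]] = True
    return flags


def elite_probability(elite_count: int, subpop_size: int) -> float:
    """O_z: fraction of the global elites residing in subpopulation z."""
    if subpop_size <= 0:
        raise ValueError("empty subpopulation")
    return elite_count / subpop_size


def update_partition_rate(o1: float, v1: float, o2: float, v2: float,
                          bounds: tuple[float, float] = PR_BOUNDS_DEFAULT) -> float:
    """PR = O1 v1 / (O1 v1 + O2 v2), clamped to ``bounds``.

    Degenerate cases fall back to 0.5: a zero denominator, or both rates at
    the numerical floor (neither engine made progress, so the elite counts
    carry no signal)."""
    num = o1 * v1
    den = num + o2 * v2
    if den <= 0.0 or (v1 <= EPS_RATE and v2 <= EPS_RATE):
        return 0.5
    return float(np.clip(num / den, bounds[0], bounds[1]))


# --------------------------------------------------------------------------
# drivers

def _evaluate_initial(problem: Problem, m: int,
                      rng: np.random.Generator) -> tuple[list[FoodSource], int]:
    pop = []
    for _ in range(m):
        v = problem.repair(problem.sample(rng))
        pop.append(FoodSource(v, problem.score(v)))
    return pop, m


def optimize(problem: Problem, config: RunConfig,
             algorithm: str = "adhdock") -> OptResult:
    """Run the hybrid (``adhdock``) or a single-strategy baseline
    (``abc``, ``de``, ``random``) to the evaluation budget; deterministic
    given ``config.seed``."""
    if algorithm not in ("adhdock", "abc", "de", "random"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    rng = np.random.default_rng(config.seed)
    if algorithm == "random":
        return _optimize_random(problem, config, rng)

    pop, evals = _evaluate_initial(problem, config.population, rng)
    best = min(pop, key=lambda fs: fs.energy).copy()
    pr = config.pr_init
    trace: list[GenerationRecord] = []
    gen = 0

    while evals < config.budget:
        gen += 1
        remaining = config.budget - evals
        if algorithm == "adhdock":
            sub1, sub2 = partition_population(pop, pr, rng)
            sub1, used1, v1 = abc_generation(
                sub1, problem.score, problem.repair, problem.sample,
                config.abc, rng, remaining)
            sub2, used2, v2 = de_generation(
                sub2, problem.score, problem.repair, config.de, rng,
                remaining - used1)
            pop = sub1 + sub2
            evals += used1 + used2
            energies = np.array([fs.energy for fs in pop])
            elites = find_elites(energies, config.elite_fraction)
            m1, m2 = len(sub1), len(sub2)
            o1 = elite_probability(int(elites[:m1].sum()), m1)
            o2 = elite_probability(int(elites[m1:].sum()), m2)
            pr = update_partition_rate(o1, v1, o2, v2, config.pr_bounds)
        elif algorithm == "abc":
            pop, used, v1 = abc_generation(
                pop, problem.score, problem.repair, problem.sample,
                config.abc, rng, remaining)
            evals += used
            m1, m2, o1, o2, v2 = len(pop), 0, 1.0, 0.0, 0.0
        else:  # de
            pop, used, v2 = de_generation(
                pop, problem.score, problem.repair, config.de, rng, remaining)
            evals += used
            m1, m2, o1, o2, v1 = 0, len(pop), 0.0, 1.0, 0.0

        gen_best = min(pop, key=lambda fs: fs.energy)
        if gen_best.energy <= best.energy:
            best = gen_best.copy()
        if gen % config.trace_every == 0 or evals >= config.budget:
            trace.append(GenerationRecord(gen, evals, best.energy, pr,
                                          m1, m2, o1, o2,
                                          v1 if algorithm != "de" else 0.0,
                                          v2 if algorithm != "abc" else 0.0))

    return OptResult(best.vector.copy(), best.energy, evals, trace)


def _optimize_random(problem: Problem, config: RunConfig,
                     rng: np.random.Generator) -> OptResult:
    """Pure random sampling baseline: best-so-far is the running minimum of
    i.i.d. draws, traced on the same generation cadence (M draws per
    'generation')."""
    best_vec, best_e = None, np.inf
    evals, gen = 0, 0
    trace: list[GenerationRecord] = []
    while evals < config.budget:
        gen += 1
        n = min(config.population, config.budget - evals)
        for _ in range(n):
            v = problem.repair(problem.sample(rng))
            e = problem.score(v)
            evals += 1
            if e <= best_e:
                best_vec, best_e = v.copy(), e
        if gen % config.trace_every == 0 or evals >= config.budget:
            trace.append(GenerationRecord(gen, evals, best_e, 0.0, 0, 0,
                                          0.0, 0.0, 0.0, 0.0))
    assert best_vec is not None
    return OptResult(best_vec, best_e, evals, trace)


def _dock_result(problem: DockingProblem, res: OptResult) -> DockResult:
    g = problem.genotype(res.best_vector)
    return DockResult(genotype=g, energy=res.best_energy,
                      breakdown=problem.breakdown(res.best_vector),
                      pose=problem.pose(res.best_vector),
                      evaluations=res.evaluations, trace=res.trace)


def run_adhdock(receptor: Receptor, ligand: Ligand, box: SearchBox,
                config: RunConfig | None = None,
                table: ForceFieldTable | None = None) -> DockResult:
    """Dock ``ligand`` into ``receptor`` with the hybrid search."""
    config = config if config is not None else RunConfig()
    problem = DockingProblem(receptor, ligand, box, table)
    return _dock_result(problem, optimize(problem, config, "adhdock"))


def run_baseline(algorithm: str, receptor: Receptor, ligand: Ligand,
                 box: SearchBox, config: RunConfig | None = None,
                 table: ForceFieldTable | None = None) -> DockResult:
    """Single-strategy baseline (``abc``, ``de`` or ``random``) with the
    same budget accounting as :func:`run_adhdock`."""
    config = config if config is not None else RunConfig()
    problem = DockingProblem(receptor, ligand, box, table)
    return _dock_result(problem, optimize(problem, config, algorithm))
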