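"""Batch benchmarking and evaluation statistics.

A docking run is summarized as a :class:`RunRecord` (best energy, best-pose
RMSD to the reference pose, evaluations, convergence trace).  Re-docking
success uses the conventional strict 2.0-Angstrom RMSD threshold.  Box-plot
summaries use linear-interpolation quartiles with Tukey 1.5*IQR whiskers,
and algorithm pairs are compared with a two-sided Mann-Whitney rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conformation import rmsd
from .fixtures import ToyComplex
from .hybrid import DockResult, RunConfig, run_adhdock, run_baseline

__all__ = [
    "RunRecord",
    "SummaryStats",
    "success_rate",
    "summarize",
    "compare_algorithms",
    "run_on_complex",
    "run_benchmark",
    "benchmark_table",
    "pairwise_tests",
]


@dataclass
class RunRecord:
    complex_id: str
    algorithm: str
    seed: int
    best_energy: float
    best_rmsd: float
    evaluations: int
    trace: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class SummaryStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def success_rate(rmsds: Sequence[float], threshold: float = 2.0
                 ) -> tuple[int, float]:
    """(count, fraction) of runs with RMSD strictly below ``threshold`` —
    an RMSD exactly at the threshold is a failure."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(rmsds, float)
    if arr.size == 0:
        raise ValueError("no RMSD values")
    count = int(np.sum(arr < threshold))
    return count, count / arr.size


def summarize(values: Sequence[float]) -> SummaryStats:
    """Five-number box-plot summary: linear-interpolation quartiles,
    whiskers at the most extreme data within 1.5*IQR of the box, points
    beyond the fences reported as outliers."""
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return SummaryStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)]),
    )


def compare_algorithms(samples_a: Sequence[float], samples_b: Sequence[float],
                       alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U rank test between two samples of best
    energies (n >= 5 each); returns (U statistic, p value, significant).
    Fully tied samples give p = 1 (no evidence of a difference)."""
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 samples per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(a.size * b.size / 2.0), 1.0, False
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p), bool(p < alpha)


def run_on_complex(toy: ToyComplex, algorithm: str, seed: int,
                   config: RunConfig | None = None) -> RunRecord:
    """Dock one toy complex once and score the result against its planted
    reference pose (heavy-atom, index-matched RMSD)."""
    base = config if config is not None else RunConfig()
    cfg = RunConfig(population=base.population, budget=base.budget,
                    pr_init=base.pr_init, pr_bounds=base.pr_bounds,
                    elite_fraction=base.elite_fraction, seed=seed,
                    abc=base.abc, de=base.de, trace_every=base.trace_every)
    if algorithm == "adhdock":
        res: DockResult = run_adhdock(toy.receptor, toy.ligand, toy.box, cfg)
    else:
        res = run_baseline(algorithm, toy.receptor, toy.ligand, toy.box, cfg)
    best_rmsd = rmsd(res.pose.coords, toy.planted_pose(),
                     atom_types=toy.ligand.types, heavy_only=True)
    return RunRecord(complex_id=toy.name, algorithm=algorithm, seed=seed,
                     best_energy=res.energy, best_rmsd=best_rmsd,
                     evaluations=res.evaluations, trace=res.convergence)


def run_benchmark(complexes: Sequence[ToyComplex], algorithms: Sequence[str],
                  seeds: Sequence[int], config: RunConfig | None = None
                  ) -> list[RunRecord]:
    """Full factorial benchmark: every complex x algorithm x seed."""
    return [run_on_complex(toy, algo, seed, config)
            for toy in complexes for algo in algorithms for seed in seeds]


def benchmark_table(records: Sequence[RunRecord]) -> pd.DataFrame:
    """Tidy per-run table with the documented column set."""
    return pd.DataFrame(
        [{"complex": r.complex_id, "algorithm": r.algorithm, "seed": r.seed,
          "best_energy": r.best_energy, "best_rmsd": r.best_rmsd,
          "evaluations": r.evaluations} for r in records],
        columns=["complex", "algorithm", "seed", "best_energy", "best_rmsd",
                 "evaluations"],
    )


def pairwise_tests(records: Sequence[RunRecord], reference: str = "adhdock",
                   n_best: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Per-complex rank tests of the reference algorithm against each other
    algorithm, on the ``n_best`` best energies per group (the ten-best
    protocol)."""
    df = benchmark_table(records)
    rows = []
    for cid, sub in df.groupby("complex", sort=False):
        ref = np.sort(sub.loc[sub.algorithm == reference, "best_energy"])[:n_best]
        for algo in sub.algorithm.unique():
            if algo == reference:
                continue
            other = np.sort(sub.loc[sub.algorithm == algo, "best_energy"])[:n_best]
            u, p, sig = compare_algorithms(ref, other, alpha)
            rows.append({"complex": cid, "algorithm": algo, "U": u,
                         "p_value": p, "significant": sig})
    return pd.DataFrame(rows, columns=["complex", "algorithm", "U", "p_value",
                                       "significant"])
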