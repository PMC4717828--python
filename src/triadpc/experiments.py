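"""Replicated simulation studies: type I error and power of the trio scans.

A study cell fixes a disease scenario (effect type, relative risks,
baseline), a sample size and a population structure, then repeats
simulate -> test -> permutation p-value over many replicates.  The
rejection rate at level alpha is the proportion of replicates with
p_hat <= alpha; its Monte-Carlo standard error is sqrt(rate(1-rate)/R).

All three scan statistics (max_PC, max_Z2 on X = 2C-F-M, max_Z2 on
Y = M-F) are computed on every replicate from the same data and the same
permutation swaps, so cells can be compared statistic-by-statistic.

Reproducibility: replicate r of a cell uses the seed stream
SeedSequence([master_seed, cell_tag, r]) regardless of how replicates are
scheduled, so results are bit-identical for any worker count.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .permutation import PermutationPlan, STATISTICS, permute_all_stats
from .simulator import (AdmixtureModel, DiseaseScenario, PopulationModel,
                        sample_affected_trios)
from .trio_stats import compute_diff_vectors

__all__ = ["DOMINANT", "RECESSIVE", "CellConfig", "CellResult",
           "run_cell", "run_grid", "summarize"]

#: (R1, R2) for the two standard risk models.
DOMINANT = (2.0, 2.0)
RECESSIVE = (1.0, 2.0)

_MAX_ATTEMPTS = 5


@dataclass(frozen=True)
class CellConfig:
    """One cell of a type-I-error / power study grid."""

    effect: str = "child"               # child | maternal | joint
    r1: float = 2.0
    r2: float = 2.0
    n_trios: int = 100
    population: str = "homogeneous"     # homogeneous | admixed
    n_replicates: int = 1000
    n_permutations: int = 500
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    baseline: float = 0.01

    def __post_init__(self):
        if self.population not in ("homogeneous", "admixed"):
            raise ValueError("population must be 'homogeneous' or 'admixed'")
        if min(self.n_trios, self.n_replicates, self.n_permutations) < 1:
            raise ValueError("counts must be positive")
        if not all(0.0 < a <= 1.0 for a in self.alphas):
            raise ValueError("alpha levels must be in (0, 1]")
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))

    @classmethod
    def null(cls, **kw) -> "CellConfig":
        return cls(effect="child", r1=1.0, r2=1.0, **kw)

    def scenario(self) -> DiseaseScenario:
        return DiseaseScenario(baseline=self.baseline, r1=self.r1,
                               r2=self.r2, effect=self.effect)

    def population_model(self):
        if self.population == "admixed":
            return AdmixtureModel.default()
        return PopulationModel()

    def tag(self) -> int:
        """Stable 32-bit hash of the cell, used to separate seed streams."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return zlib.crc32(payload.encode()) & 0x7FFFFFFF


@dataclass
class CellResult:
    """Rejection rates for one cell, plus the raw per-replicate p-values."""

    config: CellConfig
    master_seed: int
    p_values: np.ndarray = field(repr=False)    # (R, n_statistics)
    statistics: tuple[str, ...] = STATISTICS

    @property
    def n_replicates(self) -> int:
        return self.p_values.shape[0]

    def rejection_rate(self, statistic: str, alpha: float) -> float:
        j = self.statistics.index(statistic)
        return float(np.mean(self.p_values[:, j] <= alpha))

    def mc_se(self, statistic: str, alpha: float) -> float:
        r = self.rejection_rate(statistic, alpha)
        return float(np.sqrt(r * (1.0 - r) / self.n_replicates))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stat in self.statistics:
            for alpha in self.config.alphas:
                rows.append({
                    "effect": self.config.effect, "r1": self.config.r1,
                    "r2": self.config.r2, "n_trios": self.config.n_trios,
                    "population": self.config.population,
                    "statistic": stat, "alpha": alpha,
                    "rejection_rate": self.rejection_rate(stat, alpha),
                    "mc_se": self.mc_se(stat, alpha),
                    "n_replicates": self.n_replicates,
                    "n_permutations": self.config.n_permutations,
                    "seed": self.master_seed,
                })
        return pd.DataFrame(rows)


def _one_replicate(cell: CellConfig, master_seed: int, rep: int) -> list[float]:
    scenario = cell.scenario()
    model = cell.population_model()
    for attempt in range(_MAX_ATTEMPTS):
        ss = np.random.SeedSequence([master_seed, cell.tag(), rep, attempt])
        rng = np.random.default_rng(ss)
        try:
            trios = sample_affected_trios(model, scenario, cell.n_trios, rng)
            diffs = compute_diff_vectors(trios)
            plan = PermutationPlan.generate(cell.n_permutations,
                                            cell.n_trios, rng)
            results = permute_all_stats(diffs, plan)
            return [results[s].p_value for s in STATISTICS]
        except ValueError:
            if attempt == _MAX_ATTEMPTS - 1:
                raise
    raise AssertionError("unreachable")


def run_cell(cell: CellConfig, master_seed: int, n_jobs: int = 1) -> CellResult:
    """Run every replicate of one cell; deterministic for any n_jobs."""
    reps = range(cell.n_replicates)
    if n_jobs == 1:
        rows = [_one_replicate(cell, master_seed, r) for r in reps]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(cell, master_seed, r) for r in reps)
    return CellResult(config=cell, master_seed=master_seed,
                      p_values=np.asarray(rows, dtype=np.float64))


def run_grid(cells, master_seed: int, n_jobs: int = 1) -> list[CellResult]:
    return [run_cell(c, master_seed, n_jobs=n_jobs) for c in cells]


def summarize(results) -> pd.DataFrame:
    """Long-format table of rejection rates with Monte-Carlo SEs."""
    frames = [r.to_frame() for r in results]
    if not frames:
        return pd.DataFrame(columns=[
            "effect", "r1", "r2", "n_trios", "population", "statistic",
            "alpha", "rejection_rate", "mc_se", "n_replicates",
            "n_permutations", "seed"])
    return pd.concat(frames, ignore_index=True)
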