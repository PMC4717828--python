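"""Permutation inference for the max_PC and max_Z2 scan statistics.

Under the joint null (no association, no maternally mediated effect) the
labels within a trio are exchangeable in two independent ways:

* swapping the "case" and "complement" pseudo-individuals replaces C with
  F + M - C and therefore negates X = 2C - F - M while leaving Y untouched;
* swapping the mother and father labels exchanges M and F and therefore
  negates Y = M - F while leaving X untouched.

Each permutation draws both swaps independently with probability 1/2 per
trio, and a swap is applied to every locus of that trio, which preserves
the between-locus correlation the max statistic must be calibrated
against.  The statistic is recomputed on the relabelled data with exactly
the same conventions as on the observed data, and the p-value is the
proportion of permutation statistics strictly larger than the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trio_stats import (DiffVectors, MaxStatResult, _masked_scores,
                         _pc_matrix, _z2_matrix, max_pc, max_z2)

__all__ = ["PermutationPlan", "permute_stat", "permute_all_stats", "STATISTICS"]

log = logging.getLogger(__name__)

STATISTICS = ("max_pc", "max_z2_assoc", "max_z2_maternal")


@dataclass(frozen=True)
class PermutationPlan:
    """Pre-drawn trio-level label swaps for B permutations.

    ``flip_x[b, i]`` swaps case/complement for trio i in permutation b
    (negates X); ``flip_y[b, i]`` swaps the parental labels (negates Y).
    """

    flip_x: np.ndarray
    flip_y: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        fx = np.asarray(self.flip_x, dtype=bool)
        fy = np.asarray(self.flip_y, dtype=bool)
        if fx.shape != fy.shape or fx.ndim != 2 or fx.shape[0] < 1:
            raise ValueError("flip matrices must be equal-shape (B, n) with B >= 1")
        object.__setattr__(self, "flip_x", fx)
        object.__setattr__(self, "flip_y", fy)

    @property
    def n_permutations(self) -> int:
        return self.flip_x.shape[0]

    @property
    def n_trios(self) -> int:
        return self.flip_x.shape[1]

    @classmethod
    def generate(cls, n_permutations: int, n_trios: int,
                 seed: int | np.random.Generator | None = None) -> "PermutationPlan":
        """Draw the two swap indicators i.i.d. Bernoulli(1/2) per trio."""
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        flips = rng.random((2, n_permutations, n_trios)) < 0.5
        return cls(flip_x=flips[0], flip_y=flips[1],
                   seed=None if isinstance(seed, np.random.Generator) else seed)

    def signs(self):
        """(sx, sy) float sign matrices in {-1, +1}, shape (B, n)."""
        return 1.0 - 2.0 * self.flip_x, 1.0 - 2.0 * self.flip_y


def _null_matrix(diffs: DiffVectors, statistic: str, plan: PermutationPlan,
                 eigen_sign: float):
    x, y, w = _masked_scores(diffs)
    sx, sy = plan.signs()
    if statistic == "max_pc":
        mat, n_l = _pc_matrix(x, y, w, sx, sy, eigen_sign=eigen_sign)
        usable = n_l >= 2
    elif statistic == "max_z2_assoc":
        mat, n_l = _z2_matrix(x, w, sx)
        usable = n_l >= 1
    elif statistic == "max_z2_maternal":
        mat, n_l = _z2_matrix(y, w, sy)
        usable = n_l >= 1
    else:
        raise ValueError(f"unknown statistic {statistic!r}; "
                         f"expected one of {STATISTICS}")
    if not usable.any():
        raise ValueError(f"{statistic}: no usable locus")
    return np.nanmax(np.where(usable[None, :], mat, -np.inf), axis=1)


def _p_hat(null_stats: np.ndarray, observed: float,
           add_one_correction: bool) -> float:
    bigger = int(np.count_nonzero(null_stats > observed))
    if add_one_correction:
        return (bigger + 1) / (null_stats.size + 1)
    return bigger / null_stats.size


def permute_stat(diffs: DiffVectors, statistic: str, plan: PermutationPlan,
                 add_one_correction: bool = False,
                 eigen_sign: float = 1.0) -> MaxStatResult:
    """Observed max statistic plus its permutation p-value.

    Ties count as "not larger" (strict inequality), so p_hat = 0 is
    possible; ``add_one_correction`` switches to (b + 1)/(B + 1).
    """
    if statistic == "max_pc":
        result = max_pc(diffs, eigen_sign=eigen_sign)
    elif statistic == "max_z2_assoc":
        result = max_z2(diffs, "association")
    elif statistic == "max_z2_maternal":
        result = max_z2(diffs, "maternal")
    else:
        raise ValueError(f"unknown statistic {statistic!r}; "
                         f"expected one of {STATISTICS}")
    null_stats = _null_matrix(diffs, statistic, plan, eigen_sign)
    result.null_stats = null_stats
    result.p_value = _p_hat(null_stats, result.max_stat, add_one_correction)
    log.info("%s = %.4f, p_hat = %.4g (%d permutations)", statistic,
             result.max_stat, result.p_value, plan.n_permutations)
    return result


def permute_all_stats(diffs: DiffVectors, plan: PermutationPlan,
                      add_one_correction: bool = False,
                      eigen_sign: float = 1.0) -> dict[str, MaxStatResult]:
    """All three scan statistics sharing one flip matrix.

    Sharing the swaps across statistics keeps each marginal test exactly as
    in :func:`permute_stat` while amortizing the simulation of the null.
    """
    return {s: permute_stat(diffs, s, plan, add_one_correction, eigen_sign)
            for s in STATISTICS}
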